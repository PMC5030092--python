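"""Seeded generators for every input the pipeline consumes.

The generator family emulates the statistical structure the analysis
assumes: a genome carrying restriction sites at known (planted) positions,
negative-binomially distributed fragment counts with planted IP-over-input
enrichment and planted hormone induction, a gene table whose expression and
replication-timing covariates are correlated, and mutation sets placed with
configurable preference for hormone-induced genes.  Every generator records
its planted ground truth so recovery metrics are computable downstream, and
all randomness flows through one :class:`numpy.random.Generator` derived
from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from driptools.count_model import CountMatrix, SampleMeta
from driptools.e2_response import classify_induced, e2_zscore
from driptools.genome_digest import ENZYME_TABLE, EnzymeSpec, FragmentInterval

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_drip_counts",
    "simulate_gene_table",
    "simulate_mutations",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults mirror a desk-scale DRIP experiment: a small multi-contig
    genome cut roughly once per kilobase, three biological replicates of IP
    and input in mock and E2-stimulated conditions, negative-binomial
    counts with moderate overdispersion, and a gene catalogue in which a
    minority of genes responds to E2 with z-scores well past the calling
    threshold.
    """

    seed: int
    # genome
    n_contigs: int = 2
    contig_length: int = 50_000
    site_density_per_enzyme: float = 2e-4  # planted sites per bp per enzyme
    # count model
    conditions: tuple[str, ...] = ("mock", "E2_2h")
    n_replicates: int = 3
    input_mean: float = 50.0
    ip_mean: float = 50.0
    dispersion: float = 0.05
    mean_log_sd: float = 0.8  # per-fragment baseline spread (log scale)
    enriched_fraction: float = 0.2
    enriched_log2_effect: float = 2.0
    induced_fraction: float = 0.1  # of fragments; planted within the enriched set
    induced_log2_effect: float = 1.5
    library_size: int = 1_000_000
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    # gene table
    n_genes: int = 5_000
    induced_gene_fraction: float = 0.15
    induced_z_margin: float = 2.0  # planted z exceeds the threshold by at least this
    z_threshold: float = 2.0
    expression_cv: float = 0.2
    covariate_correlation: float = 0.5
    gene_length_median_bp: float = 10_000.0
    gene_length_log_sd: float = 0.6
    # mutations
    mutation_enrichment_odds: float = 3.0
    sv_base_prob: float = 0.1
    translocation_base_prob: float = 0.1
    ssm_rate_per_kb: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "site_density_per_enzyme",
            "enriched_fraction",
            "induced_fraction",
            "induced_gene_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draw parameterized by mean and dispersion (var = mu + alpha*mu^2)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_genome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with enzyme recognition sequences planted at known positions.

    Returns ``(genome, truth)`` where truth lists every planted site
    (contig, position, enzyme).  Background occurrences of the recognition
    sequences also arise by chance in the random sequence; the digest
    reports both, so the truth table is a subset of all discovered sites.
    """
    rng = cfg.rng() if rng is None else rng
    enzymes = list(ENZYME_TABLE.values())
    genome: dict[str, str] = {}
    rows = []
    for ci in range(cfg.n_contigs):
        contig = f"chr{ci + 1}"
        seq = rng.choice(list("ACGT"), size=cfg.contig_length)
        max_rec = max(len(e.recognition) for e in enzymes)
        occupied = np.zeros(cfg.contig_length, dtype=bool)
        for enz in enzymes:
            n_sites = int(round(cfg.site_density_per_enzyme * cfg.contig_length))
            placed = 0
            attempts = 0
            while placed < n_sites and attempts < 50 * max(n_sites, 1):
                attempts += 1
                pos = int(rng.integers(0, cfg.contig_length - len(enz.recognition)))
                span = slice(max(pos - max_rec, 0), pos + len(enz.recognition) + max_rec)
                if occupied[span].any():
                    continue
                seq[pos : pos + len(enz.recognition)] = list(enz.recognition)
                occupied[pos : pos + len(enz.recognition)] = True
                rows.append({"contig": contig, "position": pos, "enzyme": enz.name})
                placed += 1
        genome[contig] = "".join(seq)
    truth = pd.DataFrame(rows, columns=["contig", "position", "enzyme"])
    truth = truth.sort_values(["contig", "position"]).reset_index(drop=True)
    return genome, truth


def _design(cfg: SimulationConfig) -> list[SampleMeta]:
    meta = []
    for cond in cfg.conditions:
        for assay in ("IP", "input"):
            for rep in range(1, cfg.n_replicates + 1):
                meta.append(
                    SampleMeta(
                        sample_id=f"{cond}_{assay}_r{rep}",
                        condition=cond,
                        assay=assay,
                        replicate=rep,
                        total_mapped_reads=1,  # replaced after factors are drawn
                    )
                )
    return meta


def simulate_drip_counts(
    fragments: Sequence[FragmentInterval],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB fragment counts with planted enrichment and induction.

    Each fragment gets a log-normal baseline mean; a planted *enriched*
    subset has its IP mean multiplied by ``2**enriched_log2_effect`` in all
    conditions, and a planted *induced* subset (drawn within the enriched
    set) is additionally multiplied by ``2**induced_log2_effect`` in
    non-reference (E2) conditions, in the IP assay only.  Per-sample size
    factors scale the means and the recorded library totals alike.

    Returns ``(matrix, truth)`` with truth columns
    (fragment, enriched, induced).
    """
    rng = cfg.rng() if rng is None else rng
    frag_ids = [f.id for f in fragments]
    n_frag = len(frag_ids)
    if n_frag == 0:
        raise ValueError("no fragments to simulate over")

    base = np.exp(rng.normal(np.log(cfg.input_mean), cfg.mean_log_sd, n_frag))
    ip_scale = cfg.ip_mean / cfg.input_mean

    n_enr = int(round(cfg.enriched_fraction * n_frag))
    enriched_idx = rng.choice(n_frag, size=n_enr, replace=False)
    n_ind = min(int(round(cfg.induced_fraction * n_frag)), n_enr)
    induced_idx = rng.choice(enriched_idx, size=n_ind, replace=False) if n_ind else np.array([], dtype=int)
    enriched = np.zeros(n_frag, dtype=bool)
    enriched[enriched_idx] = True
    induced = np.zeros(n_frag, dtype=bool)
    induced[induced_idx] = True

    meta = _design(cfg)
    lo, hi = cfg.size_factor_range
    factors = rng.uniform(lo, hi, len(meta))
    counts = np.empty((n_frag, len(meta)), dtype=np.int64)
    ref_condition = cfg.conditions[0]
    final_meta = []
    for j, m in enumerate(meta):
        mu = base.copy()
        if m.assay == "IP":
            mu *= ip_scale
            mu[enriched] *= 2.0**cfg.enriched_log2_effect
            if m.condition != ref_condition:
                mu[induced] *= 2.0**cfg.induced_log2_effect
        counts[:, j] = _nb_draw(rng, mu * factors[j], cfg.dispersion)
        final_meta.append(
            SampleMeta(
                m.sample_id,
                m.condition,
                m.assay,
                m.replicate,
                int(round(cfg.library_size * factors[j])),
            )
        )
    matrix = CountMatrix.from_meta(
        pd.DataFrame(counts, index=pd.Index(frag_ids, name="fragment"),
                     columns=[m.sample_id for m in final_meta]),
        final_meta,
    )
    truth = pd.DataFrame(
        {"fragment": frag_ids, "enriched": enriched, "induced": induced}
    ).set_index("fragment")
    return matrix, truth


def simulate_gene_table(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene catalogue with planted E2-induced genes and correlated covariates.

    Mock-condition means are log-normal; per-condition standard deviations
    follow a gamma-distributed coefficient of variation around
    ``expression_cv``.  For planted induced genes the E2 mean is placed so
    the true z-score exceeds ``z_threshold`` by at least
    ``induced_z_margin`` (plus a half-normal excess); other genes get
    standard-normal z.  Replication timing is drawn correlated with log
    mean expression at ``covariate_correlation``.

    Returns ``(genes, truth)``: a frame indexed by gene id with columns
    (mu_mock, sd_mock, mu_e2, sd_e2, length_bp, repli_timing, mean_expr,
    z, class), and the planted induced-gene indicator.
    """
    rng = cfg.rng() if rng is None else rng
    n = cfg.n_genes
    gene_ids = [f"gene{str(i).zfill(5)}" for i in range(n)]

    mu_mock = np.exp(rng.normal(np.log(50.0), 1.0, n))
    cv_mock = rng.gamma(4.0, cfg.expression_cv / 4.0, n)
    cv_e2 = rng.gamma(4.0, cfg.expression_cv / 4.0, n)
    sd_mock = mu_mock * cv_mock

    n_ind = int(round(cfg.induced_gene_fraction * n))
    induced = np.zeros(n, dtype=bool)
    if n_ind:
        induced[rng.choice(n, size=n_ind, replace=False)] = True
    z_true = rng.normal(0.0, 1.0, n)
    z_true[induced] = cfg.z_threshold + cfg.induced_z_margin + np.abs(rng.normal(0.0, 1.0, int(induced.sum())))

    # sd_e2 scales with the mock mean (not the shifted E2 mean), so solving
    # mu_e2 for the target z leaves the realized z exactly on target
    sd_e2 = mu_mock * cv_e2
    mu_e2 = mu_mock + z_true * np.sqrt(sd_mock**2 + sd_e2**2)
    mu_e2 = np.maximum(mu_e2, 0.01 * mu_mock)  # expression means stay positive

    length_bp = np.maximum(
        np.exp(rng.normal(np.log(cfg.gene_length_median_bp), cfg.gene_length_log_sd, n)), 200.0
    ).astype(np.int64)
    mean_expr = (mu_mock + mu_e2) / 2.0

    log_expr = np.log(mean_expr)
    x = (log_expr - log_expr.mean()) / log_expr.std()
    rho = cfg.covariate_correlation
    repli_timing = rho * x + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal(0.0, 1.0, n)

    z = e2_zscore(mu_mock, sd_mock, mu_e2, sd_e2)
    genes = pd.DataFrame(
        {
            "mu_mock": mu_mock,
            "sd_mock": sd_mock,
            "mu_e2": mu_e2,
            "sd_e2": sd_e2,
            "length_bp": length_bp,
            "repli_timing": repli_timing,
            "mean_expr": mean_expr,
            "z": z,
            "class": classify_induced(z, cfg.z_threshold),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = pd.Series(induced, index=genes.index, name="planted_induced")
    return genes, truth


def simulate_mutations(
    genes: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mutation table across the three classes with planted preference.

    Structural variants and translocations are per-gene presence flags
    drawn with base probability ``sv_base_prob``/``translocation_base_prob``
    and odds multiplied by ``mutation_enrichment_odds`` for E2-induced
    (z > threshold) genes.  Simple somatic counts are Poisson with mean
    ``length_kb * ssm_rate_per_kb``, the rate multiplied by the same odds
    factor for induced genes.  Returns columns (gene_id, class, count).
    """
    rng = cfg.rng() if rng is None else rng
    is_induced = genes["z"].to_numpy() > cfg.z_threshold
    rows = []
    for mclass, p0 in (
        ("structural_variant", cfg.sv_base_prob),
        ("translocation", cfg.translocation_base_prob),
    ):
        odds = p0 / (1.0 - p0)
        odds_vec = np.where(is_induced, odds * cfg.mutation_enrichment_odds, odds)
        p = odds_vec / (1.0 + odds_vec)
        hit = rng.random(len(genes)) < p
        for gid in genes.index[hit]:
            rows.append({"gene_id": gid, "class": mclass, "count": 1})
    kb = genes["length_bp"].to_numpy() / 1000.0
    rate = kb * cfg.ssm_rate_per_kb * np.where(is_induced, cfg.mutation_enrichment_odds, 1.0)
    ssm = rng.poisson(rate)
    for gid, c in zip(genes.index, ssm):
        if c > 0:
            rows.append({"gene_id": gid, "class": "simple_somatic", "count": int(c)})
    return pd.DataFrame(rows, columns=["gene_id", "class", "count"])


def simulate_dataset(cfg: SimulationConfig) -> dict:
    """Generate the full input bundle with one shared generator.

    Returns a dict with keys ``genome``, ``site_truth``, ``fragments``,
    ``counts`` (CountMatrix), ``count_truth``, ``genes``, ``gene_truth``,
    ``mutations``.  Deterministic given ``cfg.seed``.
    """
    from driptools.genome_digest import digest_genome

    rng = cfg.rng()
    genome, site_truth = simulate_genome(cfg, rng)
    fragments = digest_genome(genome)
    counts, count_truth = simulate_drip_counts(fragments, cfg, rng)
    genes, gene_truth = simulate_gene_table(cfg, rng)
    mutations = simulate_mutations(genes, cfg, rng)
    return {
        "genome": genome,
        "site_truth": site_truth,
        "fragments": fragments,
        "counts": counts,
        "count_truth": count_truth,
        "genes": genes,
        "gene_truth": gene_truth,
        "mutations": mutations,
    }
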