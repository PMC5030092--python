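"""Peak calling, negative-interval backgrounds, and summary profiles.

A "DRIP peak" is a restriction fragment whose IP counts are significantly
enriched over input (positive log2 fold change, BH-adjusted p below alpha).
Differential (hormone-induced) calling then operates on the union of
positive fragments and a matched set of negative intervals, so the test
background includes unenriched regions, and can additionally require every
biological replicate to agree in direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from driptools.count_model import (
    PSEUDO_MEAN,
    CountMatrix,
    nb_wald_test,
    size_factors_per_million,
)
from driptools.genome_digest import FragmentInterval

__all__ = [
    "PeakSet",
    "DifferentialCallConfig",
    "call_peaks",
    "select_negative_intervals",
    "call_differential_peaks",
    "overlap_fraction",
    "assign_to_genes",
    "metagene_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class PeakSet:
    """A called set of fragments with their test results and provenance."""

    condition: str
    direction: str  # "enriched" | "induced" | "decreased"
    results: pd.DataFrame  # TestResult rows, indexed by fragment id
    provenance: dict = field(default_factory=dict)

    @property
    def fragment_ids(self) -> list[str]:
        return list(self.results.index)

    def __len__(self) -> int:
        return len(self.results)


@dataclass
class DifferentialCallConfig:
    """Thresholds for differential DRIP calling."""

    alpha_drip: float = 0.1
    require_replicate_consistency: bool = True
    negative_set_size_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_drip <= 1:
            raise ValueError("alpha_drip must be in (0, 1]")
        if self.negative_set_size_ratio < 0:
            raise ValueError("negative_set_size_ratio must be >= 0")


def call_peaks(
    results: pd.DataFrame, alpha: float = 0.1, condition: str = ""
) -> PeakSet:
    """Call enriched fragments: ``log2fc > 0`` and ``padj < alpha``."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    mask = (results["log2fc"] > 0) & (results["padj"] < alpha)
    return PeakSet(
        condition=condition,
        direction="enriched",
        results=results.loc[mask.fillna(False)],
        provenance={"rule": "log2fc>0 & padj<alpha", "alpha": alpha},
    )


def select_negative_intervals(
    fragments: Sequence[FragmentInterval],
    positive_ids: Sequence[str],
    n: int,
    seed: int,
) -> list[FragmentInterval]:
    """Sample ``n`` unenriched fragments length-matched to the positive set.

    Candidate (non-positive) fragments are stratified over the length
    deciles of the positive set and sampled proportionally to the positive
    length distribution; a stratum short of candidates borrows from the
    nearest stratum (with a warning).  Deterministic given ``seed``.
    """
    if n == 0:
        return []
    positive = set(positive_ids)
    candidates = [f for f in fragments if f.id not in positive]
    if len(candidates) < n:
        raise ValueError(f"only {len(candidates)} non-positive fragments for n={n}")
    pos_lengths = np.array([f.length for f in fragments if f.id in positive])
    if pos_lengths.size == 0:
        raise ValueError("positive set is empty; cannot length-match")

    # value-binned strata from the positive length deciles; targets follow
    # the positive bin occupancy so the sampled length distribution matches
    inner_edges = np.quantile(pos_lengths, np.linspace(0, 1, 11))[1:-1]
    cand_lengths = np.array([f.length for f in candidates])
    strata = np.searchsorted(inner_edges, cand_lengths, side="left")
    pos_strata = np.searchsorted(inner_edges, pos_lengths, side="left")
    pos_counts = np.bincount(pos_strata, minlength=10).astype(float)

    raw = n * pos_counts / pos_counts.sum()
    targets = np.floor(raw).astype(int)
    remainder = raw - targets
    for s in np.argsort(-remainder, kind="mergesort")[: n - targets.sum()]:
        targets[s] += 1

    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    available = [list(np.flatnonzero(strata == s)) for s in range(10)]
    for s in range(10):
        want = int(targets[s])
        pool = available[s]
        take = min(want, len(pool))
        if take:
            picked = rng.choice(len(pool), size=take, replace=False)
            for i in sorted(picked, reverse=True):
                chosen.append(pool.pop(i))
        short = want - take
        if short:
            logger.warning(
                "negative-interval stratum %d short by %d; borrowing from nearest strata", s, short
            )
            for dist in range(1, 10):
                for t in (s - dist, s + dist):
                    if short == 0 or not 0 <= t <= 9:
                        continue
                    pool_t = available[t]
                    take_t = min(short, len(pool_t))
                    if take_t:
                        picked = rng.choice(len(pool_t), size=take_t, replace=False)
                        for i in sorted(picked, reverse=True):
                            chosen.append(pool_t.pop(i))
                        short -= take_t
                if short == 0:
                    break
    return [candidates[i] for i in sorted(chosen)]


def per_replicate_log2fc(
    matrix: CountMatrix,
    ref_samples: Sequence[str],
    alt_samples: Sequence[str],
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Pairwise per-replicate log2 fold changes on normalized counts.

    Reference and treatment samples are paired by replicate number; each
    pair yields ``log2((alt/f + c)/(ref/f + c))`` per fragment.
    """
    if size_factors is None:
        size_factors = size_factors_per_million(matrix.samples)
    ref_by_rep = {matrix.samples.loc[s, "replicate"]: s for s in ref_samples}
    alt_by_rep = {matrix.samples.loc[s, "replicate"]: s for s in alt_samples}
    common = sorted(set(ref_by_rep) & set(alt_by_rep))
    if not common:
        raise ValueError("no replicate numbers shared between the two conditions")
    out = {}
    for rep in common:
        r, a = ref_by_rep[rep], alt_by_rep[rep]
        norm_r = matrix.counts[r].to_numpy(float) / size_factors.loc[r]
        norm_a = matrix.counts[a].to_numpy(float) / size_factors.loc[a]
        out[f"rep{rep}"] = np.log2(norm_a + PSEUDO_MEAN) - np.log2(norm_r + PSEUDO_MEAN)
    return pd.DataFrame(out, index=matrix.counts.index)


def call_differential_peaks(
    matrix: CountMatrix,
    ref_condition: str,
    alt_condition: str,
    config: DifferentialCallConfig | None = None,
    assay: str = "IP",
) -> tuple[PeakSet, PeakSet]:
    """Call hormone-induced and -decreased fragments between two conditions.

    Runs the joint NB test on the supplied region set (positives plus
    matched negatives), then calls induced fragments as ``log2fc > 0`` and
    ``padj < alpha_drip``; with the replicate-consistency rule on, every
    per-replicate pairwise fold change must also be positive.  Decreased
    calls are symmetric.  Returns ``(induced, decreased)``.
    """
    config = config or DifferentialCallConfig()
    ref = matrix.select_samples(condition=ref_condition, assay=assay)
    alt = matrix.select_samples(condition=alt_condition, assay=assay)
    if config.require_replicate_consistency and (len(ref) < 2 or len(alt) < 2):
        raise ValueError("replicate-consistency rule needs >= 2 replicates per condition")
    sf = size_factors_per_million(matrix.samples)
    results = nb_wald_test(matrix, ref, alt, size_factors=sf)

    up = (results["log2fc"] > 0) & (results["padj"] < config.alpha_drip)
    down = (results["log2fc"] < 0) & (results["padj"] < config.alpha_drip)
    if config.require_replicate_consistency:
        rep_lfc = per_replicate_log2fc(matrix, ref, alt, sf)
        up &= (rep_lfc > 0).all(axis=1)
        down &= (rep_lfc < 0).all(axis=1)

    prov = {
        "ref": ref_condition,
        "alt": alt_condition,
        "assay": assay,
        "alpha_drip": config.alpha_drip,
        "replicate_consistency": config.require_replicate_consistency,
    }
    induced = PeakSet(alt_condition, "induced", results.loc[up.fillna(False)], dict(prov))
    decreased = PeakSet(alt_condition, "decreased", results.loc[down.fillna(False)], dict(prov))
    return induced, decreased


def overlap_fraction(set_a: Sequence[str] | PeakSet, set_b: Sequence[str] | PeakSet) -> float:
    """Fraction of A's members (by fragment id) also present in B."""
    a = set(set_a.fragment_ids if isinstance(set_a, PeakSet) else set_a)
    b = set(set_b.fragment_ids if isinstance(set_b, PeakSet) else set_b)
    if not a:
        logger.warning("overlap_fraction: set A is empty; returning 0.0")
        return 0.0
    return len(a & b) / len(a)


def _interval_gene_distance(
    p_start: int, p_end: int, g_start: int, g_end: int
) -> int:
    """Gap in bp between two half-open intervals; 0 when they overlap or touch."""
    return max(0, g_start - p_end, p_start - g_end)


def assign_to_genes(
    peaks: Sequence[FragmentInterval],
    genes: pd.DataFrame,
    max_distance: int = 1000,
) -> pd.DataFrame:
    """Assign each peak to its nearest gene within ``max_distance`` bp.

    Distance is to the gene body (0 inside the gene); ties break by smaller
    distance, then lexicographic gene id.  ``genes`` needs columns
    (gene_id, contig, start, end).  Returns (peak_id, gene_id, distance)
    for assigned peaks only.
    """
    rows = []
    genes_by_contig = {c: g.sort_values("start") for c, g in genes.groupby("contig")}
    for peak in peaks:
        g = genes_by_contig.get(peak.contig)
        if g is None:
            continue
        dists = np.maximum(
            0,
            np.maximum(
                g["start"].to_numpy() - peak.end, peak.start - g["end"].to_numpy()
            ),
        )
        ok = dists <= max_distance
        if not ok.any():
            continue
        sub = pd.DataFrame({"gene_id": g["gene_id"].to_numpy()[ok], "distance": dists[ok]})
        best = sub.sort_values(["distance", "gene_id"]).iloc[0]
        rows.append({"peak_id": peak.id, "gene_id": best["gene_id"], "distance": int(best["distance"])})
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"])


def metagene_profile(
    coverage: Mapping[str, np.ndarray],
    genes: pd.DataFrame,
    flank: int = 2000,
    body_bins: int = 100,
    flank_bins: int = 20,
) -> np.ndarray:
    """Mean coverage profile over 5' flank, length-scaled gene body, 3' flank.

    ``coverage`` maps contig to a per-base array; positions outside the
    contig contribute 0.  Minus-strand genes are reversed so bin 0 is always
    the 5' flank edge.  Returns a vector of length
    ``flank_bins + body_bins + flank_bins`` of per-bin means across genes.
    ``genes`` needs columns (contig, start, end, strand).
    """
    n_bins = flank_bins + body_bins + flank_bins
    profiles = []
    for _, gene in genes.iterrows():
        cov = coverage.get(gene["contig"])
        if cov is None:
            continue
        start, end = int(gene["start"]), int(gene["end"])
        padded_start = start - flank
        padded_end = end + flank
        window = np.zeros(padded_end - padded_start)
        lo, hi = max(padded_start, 0), min(padded_end, len(cov))
        if hi > lo:
            window[lo - padded_start : hi - padded_start] = cov[lo:hi]

        edges = np.concatenate(
            [
                np.linspace(0, flank, flank_bins + 1)[:-1],
                np.linspace(flank, flank + (end - start), body_bins + 1)[:-1],
                np.linspace(flank + (end - start), len(window), flank_bins + 1),
            ]
        )
        prof = np.empty(n_bins)
        for i in range(n_bins):
            a, b = int(np.floor(edges[i])), int(np.ceil(edges[i + 1]))
            b = max(b, a + 1)
            prof[i] = window[a : min(b, len(window))].mean()
        if gene["strand"] == "-":
            prof = prof[::-1]
        profiles.append(prof)
    if not profiles:
        return np.zeros(n_bins)
    return np.mean(profiles, axis=0)
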