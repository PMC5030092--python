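"""Fragment-level counting, filtering, normalization and NB testing.

Read counts over restriction fragments are overdispersed relative to
Poisson, so enrichment (IP over input) and differential (E2 over mock)
testing uses a negative-binomial model with variance ``mu + alpha*mu**2``.
The test implemented here is a two-group Wald test on the log2 ratio of
normalized group means, with a delta-method standard error; it needs no
covariates because every contrast in the pipeline is a two-group design.

Normalization follows total mapped reads: each sample's size factor is its
library total divided by the geometric mean of all totals, so normalized
counts stay on the scale of the raw data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from driptools.genome_digest import FragmentInterval

__all__ = [
    "SampleMeta",
    "CountMatrix",
    "five_prime_positions",
    "count_reads_to_fragments",
    "filter_low_coverage",
    "size_factors_total_mapped",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "rpkm",
    "ALPHA_MIN",
]

logger = logging.getLogger(__name__)

#: Dispersion floor; at this value the model is effectively Poisson.
ALPHA_MIN = 1e-8

#: Pseudo-mean guarding log2 fold changes against zero group means.
PSEUDO_MEAN = 0.5


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing library."""

    sample_id: str
    condition: str
    assay: str  # "IP" or "input"
    replicate: int
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.assay not in ("IP", "input"):
            raise ValueError(f"assay must be 'IP' or 'input', got {self.assay!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be > 0")


@dataclass
class CountMatrix:
    """Fragment x sample counts plus per-sample metadata.

    ``counts`` is indexed by fragment id with one column per sample id;
    ``samples`` is indexed by sample id with columns
    (condition, assay, replicate, total_mapped_reads).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns must match samples index, in order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.isfinite(self.counts.to_numpy()).all():
            raise ValueError("counts must be finite")
        key = self.samples[["condition", "assay", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate (condition, assay, replicate): {tuple(dup)}")
        if (self.samples["total_mapped_reads"] <= 0).any():
            raise ValueError("total_mapped_reads must be > 0")

    @classmethod
    def from_meta(cls, counts: pd.DataFrame, meta: Iterable[SampleMeta]) -> "CountMatrix":
        samples = pd.DataFrame(
            [
                {
                    "condition": m.condition,
                    "assay": m.assay,
                    "replicate": m.replicate,
                    "total_mapped_reads": m.total_mapped_reads,
                }
                for m in meta
            ],
            index=pd.Index([m.sample_id for m in meta], name="sample_id"),
        )
        return cls(counts=counts.loc[:, samples.index], samples=samples)

    def select_samples(self, condition: str | None = None, assay: str | None = None) -> list[str]:
        """Sample ids matching the given condition and/or assay."""
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if assay is not None:
            mask &= self.samples["assay"] == assay
        return list(self.samples.index[mask])

    def subset_fragments(self, fragment_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(fragment_ids)], self.samples)


def five_prime_positions(reads: pd.DataFrame) -> pd.DataFrame:
    """Reduce stranded read intervals to their 5' genomic position.

    Plus-strand (or unstranded) reads contribute ``start``; minus-strand
    reads contribute ``end - 1``.  Returns columns (contig, pos).
    """
    if "pos" in reads.columns:
        return reads[["contig", "pos"]].copy()
    pos = reads["start"].to_numpy().copy()
    if "strand" in reads.columns:
        minus = (reads["strand"] == "-").to_numpy()
        pos[minus] = reads["end"].to_numpy()[minus] - 1
    return pd.DataFrame({"contig": reads["contig"].to_numpy(), "pos": pos})


def count_reads_to_fragments(
    reads: pd.DataFrame, fragments: Sequence[FragmentInterval]
) -> pd.Series:
    """Count reads per fragment by the fragment containing each read's 5' start.

    Fragments are assumed to tile their contigs (the digest guarantees it);
    each read lands in exactly one fragment.  Reads on contigs absent from
    the fragment set, or with positions outside the tiled range, are dropped
    and the drop count is logged.
    """
    frag_ids = [f.id for f in fragments]
    counts = pd.Series(0, index=pd.Index(frag_ids, name="fragment"), dtype=np.int64)
    if len(reads) == 0:
        return counts

    by_contig: dict[str, list[FragmentInterval]] = {}
    for f in fragments:
        by_contig.setdefault(f.contig, []).append(f)
    bounds = {}
    for contig, frs in by_contig.items():
        frs.sort(key=lambda f: f.start)
        starts = np.array([f.start for f in frs])
        bounds[contig] = (starts, frs[-1].end, [f.id for f in frs])

    pos_df = five_prime_positions(reads)
    dropped = 0
    for contig, grp in pos_df.groupby("contig", sort=False):
        if contig not in bounds:
            dropped += len(grp)
            logger.warning("dropping %d reads on contig %r absent from fragments", len(grp), contig)
            continue
        starts, contig_end, ids = bounds[contig]
        pos = grp["pos"].to_numpy()
        ok = (pos >= starts[0]) & (pos < contig_end)
        dropped += int((~ok).sum())
        idx = np.searchsorted(starts, pos[ok], side="right") - 1
        binned = np.bincount(idx, minlength=len(ids))
        counts.loc[ids] += binned
    if dropped:
        logger.info("count_reads_to_fragments: dropped %d off-contig reads", dropped)
    return counts


def filter_low_coverage(
    matrix: CountMatrix, min_count: int = 10, mode: str = "any"
) -> CountMatrix:
    """Remove fragments with fewer than ``min_count`` reads.

    ``mode="any"`` (default) removes a fragment when *any* sample is below
    the threshold — i.e. it is kept only when its minimum count across
    samples reaches ``min_count``.  ``mode="all"`` removes a fragment only
    when every sample is below the threshold.  Row order is preserved and
    the operation is idempotent.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    if len(matrix.counts) == 0:
        return matrix
    arr = matrix.counts.to_numpy()
    if mode == "any":
        keep = arr.min(axis=1) >= min_count
    else:
        keep = arr.max(axis=1) >= min_count
    return CountMatrix(matrix.counts.loc[keep], matrix.samples)


def size_factors_total_mapped(samples: pd.DataFrame | Iterable[SampleMeta]) -> pd.Series:
    """Size factors from library totals: ``total_s / geomean(totals)``.

    Normalized counts are ``count / factor``; the geometric-mean anchoring
    keeps them on the raw-count scale.
    """
    if not isinstance(samples, pd.DataFrame):
        meta = list(samples)
        samples = pd.DataFrame(
            {"total_mapped_reads": [m.total_mapped_reads for m in meta]},
            index=pd.Index([m.sample_id for m in meta], name="sample_id"),
        )
    totals = samples["total_mapped_reads"].astype(float)
    if (totals <= 0).any():
        raise ValueError("total_mapped_reads must be > 0")
    geomean = float(np.exp(np.mean(np.log(totals))))
    return totals / geomean


def size_factors_per_million(samples: pd.DataFrame, scale: float = 1e6) -> pd.Series:
    """Size factors anchored to a fixed library size: ``total_s / scale``.

    Normalized counts are then counts per ``scale`` mapped reads.  Unlike
    the geometric-mean anchoring of :func:`size_factors_total_mapped`,
    rescaling one sample's counts and total together leaves every sample's
    normalized counts — and hence every downstream test result — exactly
    unchanged, so this is the default normalization of the NB test.
    """
    totals = samples["total_mapped_reads"].astype(float)
    if (totals <= 0).any():
        raise ValueError("total_mapped_reads must be > 0")
    return totals / scale


def _group_moments(
    matrix: CountMatrix, sample_ids: Sequence[str], size_factors: pd.Series
) -> tuple[np.ndarray, np.ndarray, int]:
    norm = matrix.counts[list(sample_ids)].to_numpy(dtype=float) / size_factors.loc[
        list(sample_ids)
    ].to_numpy()
    n = norm.shape[1]
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1) if n >= 2 else np.zeros_like(mean)
    return mean, var, n


def estimate_dispersion(
    matrix: CountMatrix,
    groups: Mapping[str, Sequence[str]],
    size_factors: pd.Series,
    alpha_min: float = ALPHA_MIN,
    method: str = "per_fragment",
) -> pd.Series:
    """Method-of-moments NB dispersion per fragment.

    For each group with >= 2 replicates, ``alpha_g = (var - mean) / mean**2``
    on normalized counts; the per-fragment estimate is the max over groups,
    floored at ``alpha_min``.  With ``method="pooled"`` the per-fragment
    estimates are replaced by a single moment estimate pooled across all
    fragments, ``sum(var - mean) / sum(mean**2)`` — far more stable at the
    2-3 replicates typical of DRIP designs, where per-fragment variances
    carry only 1-2 degrees of freedom.
    """
    if method not in ("per_fragment", "pooled"):
        raise ValueError(f"method must be 'per_fragment' or 'pooled', got {method!r}")
    if not any(len(ids) >= 2 for ids in groups.values()):
        raise ValueError("at least one group needs >= 2 samples to estimate dispersion")

    n_frag = len(matrix.counts)
    if method == "pooled":
        num = 0.0
        den = 0.0
        for ids in groups.values():
            if len(ids) < 2:
                continue
            mean, var, _ = _group_moments(matrix, ids, size_factors)
            ok = mean > 0
            num += float((var[ok] - mean[ok]).sum())
            den += float((mean[ok] ** 2).sum())
        alpha = num / den if den > 0 else alpha_min
        return pd.Series(max(alpha, alpha_min), index=matrix.counts.index, name="alpha")

    alpha = np.full(n_frag, -np.inf)
    for ids in groups.values():
        if len(ids) < 2:
            continue
        mean, var, _ = _group_moments(matrix, ids, size_factors)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mean > 0, (var - mean) / np.maximum(mean, 1e-300) ** 2, alpha_min)
        alpha = np.maximum(alpha, a)
    alpha = np.maximum(alpha, alpha_min)
    return pd.Series(alpha, index=matrix.counts.index, name="alpha")


def nb_wald_test(
    matrix: CountMatrix,
    ref_samples: Sequence[str],
    alt_samples: Sequence[str],
    size_factors: pd.Series | None = None,
    dispersion: pd.Series | float | None = None,
    pseudo_mean: float = PSEUDO_MEAN,
) -> pd.DataFrame:
    """Two-group NB Wald test per fragment (treatment ``alt`` over reference ``ref``).

    Group means are fit on the normalized scale; the reported effect is
    ``log2fc = log2((mu_alt + c) / (mu_ref + c))`` with pseudo-mean
    ``c = 0.5`` so zero-count groups stay finite.  The standard error comes
    from the delta method on the NB variance ``mu + alpha*mu**2`` of each
    sample (with per-sample size factors), and the two-sided p-value from
    the Wald statistic against the standard normal.  BH-adjusted p-values
    are included.

    Returns a DataFrame indexed by fragment id with columns
    (baseMean, log2fc, se, pvalue, padj).
    """
    ref_samples, alt_samples = list(ref_samples), list(alt_samples)
    if not ref_samples or not alt_samples:
        raise ValueError("both groups must be non-empty")
    if size_factors is None:
        size_factors = size_factors_per_million(matrix.samples)
    if dispersion is None:
        dispersion = estimate_dispersion(
            matrix,
            {"ref": ref_samples, "alt": alt_samples},
            size_factors,
            method="pooled",
        )
    if np.isscalar(dispersion):
        dispersion = pd.Series(float(dispersion), index=matrix.counts.index)
    alpha = np.maximum(dispersion.loc[matrix.counts.index].to_numpy(dtype=float), ALPHA_MIN)

    def group_stats(ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        f = size_factors.loc[ids].to_numpy()
        norm = matrix.counts[ids].to_numpy(dtype=float) / f
        mu = norm.mean(axis=1)
        # NB variance mu + alpha*mu^2 on the normalized scale; the test then
        # depends on the data only through normalized counts, making results
        # exactly invariant to jointly rescaling a library's counts and total
        var_mean = (mu + alpha * mu**2) / len(ids)
        return mu, var_mean

    mu_r, var_r = group_stats(ref_samples)
    mu_t, var_t = group_stats(alt_samples)

    log2fc = np.log2(mu_t + pseudo_mean) - np.log2(mu_r + pseudo_mean)
    ln2 = np.log(2.0)
    var_lfc = var_t / ((mu_t + pseudo_mean) * ln2) ** 2 + var_r / ((mu_r + pseudo_mean) * ln2) ** 2
    se = np.sqrt(var_lfc)

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / np.maximum(se, 1e-300), 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))
    pvalue = np.clip(pvalue, 0.0, 1.0)

    all_ids = ref_samples + alt_samples
    base_mean = (
        matrix.counts[all_ids].to_numpy(dtype=float)
        / size_factors.loc[all_ids].to_numpy()
    ).mean(axis=1)

    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "pvalue": pvalue,
        },
        index=matrix.counts.index.rename("fragment"),
    )
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def bh_adjust(pvalues: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity, capped at 1.

    NaN inputs propagate as NaN and do not enter the ranking.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[valid] = res
    return out


def rpkm(
    counts: pd.DataFrame | pd.Series,
    lengths_bp: pd.Series | np.ndarray,
    totals: pd.Series | Mapping[str, int] | float,
) -> pd.DataFrame | pd.Series:
    """Reads per kilobase of interval per million mapped reads.

    ``rpkm = count / (length_kb * total / 1e6)`` per sample.
    """
    lengths = np.asarray(
        lengths_bp.loc[counts.index] if isinstance(lengths_bp, pd.Series) else lengths_bp,
        dtype=float,
    )
    if (lengths <= 0).any():
        raise ValueError("interval lengths must be > 0")
    kb = lengths / 1000.0
    if isinstance(counts, pd.Series):
        total = float(totals) if np.isscalar(totals) else float(totals[counts.name])
        return counts / (kb * total / 1e6)
    out = {}
    for col in counts.columns:
        total = float(totals) if np.isscalar(totals) else float(
            totals[col] if not isinstance(totals, pd.Series) else totals.loc[col]
        )
        out[col] = counts[col].to_numpy() / (kb * total / 1e6)
    return pd.DataFrame(out, index=counts.index)
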