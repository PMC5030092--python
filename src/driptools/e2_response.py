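"""Estrogen-responsiveness z-scores and DRIP x GRO-seq categorization.

A gene's response to 17beta-estradiol (E2) is summarized from per-condition
expression means and standard deviations as

    z = (mu_E2 - mu_mock) / sqrt(sigma_E2**2 + sigma_mock**2)

and genes with z strictly greater than 2 are classed as E2-induced.

Induced DRIP fragments are cross-categorized against GRO-seq (nascent
transcription) fold changes into four sign quadrants, applied only where
both tests are significant at their respective thresholds.  The published
GRO-seq threshold appears both as adjusted p < 0.5 and as p < 0.9 in
different places; both are shipped as named presets and the parameter is
always explicit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "GRO_ALPHA_PROSE",
    "GRO_ALPHA_CRITERIA",
    "QUADRANTS",
    "e2_zscore",
    "classify_induced",
    "categorize_drip_groseq",
]

#: GRO-seq adjusted-p threshold as stated in the methods prose.
GRO_ALPHA_PROSE = 0.5
#: GRO-seq adjusted-p threshold as stated in the figure criteria list.
GRO_ALPHA_CRITERIA = 0.9

QUADRANTS = (
    "up_drip_up_gro",
    "up_drip_down_gro",
    "down_drip_up_gro",
    "down_drip_down_gro",
    "unclassified",
)


def e2_zscore(mu_mock, sigma_mock, mu_e2, sigma_e2):
    """E2-induction z-score ``(mu_E2 - mu_mock)/sqrt(sigma_E2^2 + sigma_mock^2)``.

    Vectorized over array inputs.  When both standard deviations are zero
    the score is 0 for equal means and signed infinity (a sentinel, not a
    usable score) otherwise.
    """
    mu_mock = np.asarray(mu_mock, dtype=float)
    mu_e2 = np.asarray(mu_e2, dtype=float)
    sigma_mock = np.asarray(sigma_mock, dtype=float)
    sigma_e2 = np.asarray(sigma_e2, dtype=float)
    if (sigma_mock < 0).any() or (sigma_e2 < 0).any():
        raise ValueError("standard deviations must be >= 0")
    denom = np.sqrt(sigma_e2**2 + sigma_mock**2)
    diff = mu_e2 - mu_mock
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            denom > 0,
            diff / np.where(denom > 0, denom, 1.0),
            np.where(diff == 0, 0.0, np.sign(diff) * np.inf),
        )
    return z if z.ndim else float(z)


def classify_induced(z, threshold: float = 2.0):
    """Classify genes as E2-induced iff ``z > threshold`` (strict).

    ``z == threshold`` is non_induced.  Returns "induced"/"non_induced"
    (array of strings for array input).
    """
    z = np.asarray(z, dtype=float)
    out = np.where(z > threshold, "induced", "non_induced")
    return out if out.ndim else str(out)


def categorize_drip_groseq(
    drip: pd.DataFrame,
    gro: pd.DataFrame,
    alpha_gro: float,
    alpha_drip: float = 0.1,
) -> pd.Series:
    """Quadrant labels from paired DRIP and GRO-seq differential results.

    Both frames must be indexed by the same region ids and carry
    ``log2fc`` and ``padj``.  A region is labeled only when
    ``padj_drip < alpha_drip`` and ``padj_gro < alpha_gro``; the quadrant
    is the sign pair of the two fold changes.  ``alpha_gro`` has no
    default: pass :data:`GRO_ALPHA_PROSE` (0.5) or
    :data:`GRO_ALPHA_CRITERIA` (0.9) for the published presets.
    """
    if not drip.index.equals(gro.index):
        common = drip.index.intersection(gro.index)
        if len(common) == 0:
            raise ValueError("DRIP and GRO-seq results share no regions")
        drip, gro = drip.loc[common], gro.loc[common]
    sig = (drip["padj"] < alpha_drip) & (gro["padj"] < alpha_gro)
    labels = pd.Series("unclassified", index=drip.index, name="quadrant")
    up_d = drip["log2fc"] > 0
    up_g = gro["log2fc"] > 0
    labels[sig & up_d & up_g] = "up_drip_up_gro"
    labels[sig & up_d & ~up_g] = "up_drip_down_gro"
    labels[sig & ~up_d & up_g] = "down_drip_up_gro"
    labels[sig & ~up_d & ~up_g] = "down_drip_down_gro"
    # exact-zero fold changes carry no sign; leave them unclassified
    labels[sig & ((drip["log2fc"] == 0) | (gro["log2fc"] == 0))] = "unclassified"
    return labels
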