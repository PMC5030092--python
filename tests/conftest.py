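import numpy as np
import pandas as pd
import pytest

from driptools.count_model import CountMatrix


def nb_draw(rng, mean, alpha, size=None):
    """NB sample with variance mu + alpha*mu**2 (the model's parameterization)."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def naive_site_scan(sequence, enzymes):
    """Independent O(L*k) sliding-window oracle for restriction-site search.

    Compares every window of each recognition length against the recognition
    sequence with exact base identity (vectorized windows, no regex).
    Returns sorted (position, enzyme_name) tuples.
    """
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    hits = []
    for enz in enzymes:
        rec = np.frombuffer(enz.recognition.encode("ascii"), dtype=np.uint8)
        k = len(rec)
        if len(seq) < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(seq, k)
        match = (windows == rec).all(axis=1)
        hits.extend((int(p), enz.name) for p in np.flatnonzero(match))
    return sorted(hits)


def make_matrix(counts, totals=None, conditions=None, assays=None, replicates=None):
    """CountMatrix from a 2D array with minimal metadata."""
    counts = np.asarray(counts)
    n_frag, n_samp = counts.shape
    sids = [f"s{i}" for i in range(n_samp)]
    totals = [1_000_000] * n_samp if totals is None else list(totals)
    conditions = ["c0"] * n_samp if conditions is None else list(conditions)
    assays = ["IP"] * n_samp if assays is None else list(assays)
    if replicates is None:
        seen = {}
        replicates = []
        for c, a in zip(conditions, assays):
            seen[(c, a)] = seen.get((c, a), 0) + 1
            replicates.append(seen[(c, a)])
    samples = pd.DataFrame(
        {
            "condition": conditions,
            "assay": assays,
            "replicate": replicates,
            "total_mapped_reads": totals,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    frame = pd.DataFrame(
        counts, index=pd.Index([f"f{i}" for i in range(n_frag)], name="fragment"), columns=sids
    )
    return CountMatrix(frame, samples)


def two_group_matrix(rng, mu, alpha, n_rep=3, planted_idx=None, planted_log2fc=0.0):
    """3v3-style NB matrix: reference condition then treatment condition.

    ``mu`` is the per-fragment baseline mean (1D array); planted fragments
    get the treatment mean multiplied by 2**planted_log2fc.
    """
    base = np.atleast_1d(np.asarray(mu, dtype=float))
    mus = np.tile(base[:, None], (1, 2 * n_rep))
    if planted_idx is not None:
        mus[np.asarray(planted_idx), n_rep:] *= 2.0 ** planted_log2fc
    counts = nb_draw(rng, mus, alpha)
    m = make_matrix(
        counts,
        conditions=["ref"] * n_rep + ["alt"] * n_rep,
        assays=["IP"] * (2 * n_rep),
    )
    ref = m.select_samples(condition="ref")
    alt = m.select_samples(condition="alt")
    return m, ref, alt


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
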