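"""Shared readers/writers with provenance headers.

All tabular output is TSV (never CSV), UTF-8, with a deterministic column
order, and begins with a provenance comment block recording the tool
version, subcommand, full parameter set and seed.  Genomic coordinates are
0-based half-open (the BED dialect) everywhere; 1-based input is only ever
converted under an explicit flag, never guessed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from driptools import __version__
from driptools.genome_digest import FragmentInterval

__all__ = [
    "SchemaError",
    "provenance_header",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "write_fragments_bed",
    "read_bedgraph",
    "write_bedgraph",
    "bedgraph_to_dense",
    "read_table",
    "write_table",
]

logger = logging.getLogger(__name__)

BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


class SchemaError(ValueError):
    """Raised when a table is missing a required column."""


def provenance_header(subcommand: str, params: Mapping[str, object] | None = None) -> list[str]:
    """Comment lines recording version, subcommand and parameters."""
    lines = [f"# driptools v{__version__}", f"# subcommand: {subcommand}"]
    for key, value in sorted((params or {}).items()):
        lines.append(f"# {key}: {value}")
    return lines


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into contig -> uppercase sequence.

    CRLF line endings are accepted; an empty file is an error.
    """
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=contig, description="") for contig, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Biopython's writer wraps at its own fixed width


def read_bed(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read BED3/BED6 into (contig, start, end[, name, score, strand]).

    Comment (#), track and browser lines are skipped.  Input is sorted with
    the stable key (contig, start, end).  ``one_based=True`` shifts starts
    down by one; the convention is never auto-detected.
    """
    rows = []
    with open(path, newline=None) as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line with fewer than 3 fields: {line!r}")
            rows.append(parts[:6])
    n_cols = max(len(r) for r in rows) if rows else 3
    cols = BED_COLUMNS[:n_cols]
    df = pd.DataFrame([r + ["."] * (n_cols - len(r)) for r in rows], columns=cols)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if one_based:
        df["start"] -= 1
    return df.sort_values(["contig", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_bed(
    intervals: pd.DataFrame,
    path: str | Path,
    provenance: Sequence[str] = (),
) -> None:
    """Write BED with optional provenance comment lines first."""
    cols = [c for c in BED_COLUMNS if c in intervals.columns]
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(line + "\n")
        intervals[cols].to_csv(fh, sep="\t", header=False, index=False)


def write_fragments_bed(
    fragments: Iterable[FragmentInterval],
    path: str | Path,
    provenance: Sequence[str] = (),
    scores: Mapping[str, float] | None = None,
) -> None:
    """Fragments as BED6 (name = fragment id, score 0 unless given, strand '.').

    When ``scores`` are adjusted p-values, callers pass -10*log10(padj)
    capped at 1000 (computed upstream).
    """
    df = pd.DataFrame(
        [
            {
                "contig": f.contig,
                "start": f.start,
                "end": f.end,
                "name": f.id,
                "score": 0 if scores is None else scores.get(f.id, 0),
                "strand": ".",
            }
            for f in fragments
        ],
        columns=BED_COLUMNS,
    )
    write_bed(df, path, provenance)


def read_bedgraph(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    """Read a bedGraph into contig -> [(start, end, value)].

    Intervals are sorted per contig; overlapping intervals are an error;
    gaps mean coverage 0 (materialized by :func:`bedgraph_to_dense`).
    """
    cov: dict[str, list[tuple[int, int, float]]] = {}
    with open(path, newline=None) as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            contig, start, end, value = line.split("\t")[:4]
            cov.setdefault(contig, []).append((int(start), int(end), float(value)))
    for contig, ivs in cov.items():
        ivs.sort()
        for (s0, e0, _), (s1, _, _) in zip(ivs[:-1], ivs[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping bedGraph intervals on {contig} at {s1} < {e0}")
    return cov


def write_bedgraph(
    cov: Mapping[str, Sequence[tuple[int, int, float]]],
    path: str | Path,
    provenance: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(line + "\n")
        for contig in sorted(cov):
            for start, end, value in cov[contig]:
                fh.write(f"{contig}\t{start}\t{end}\t{value:g}\n")


def bedgraph_to_dense(
    cov: Mapping[str, Sequence[tuple[int, int, float]]],
    contig_lengths: Mapping[str, int],
) -> dict[str, np.ndarray]:
    """Materialize step intervals into per-base arrays (gaps are 0)."""
    dense = {}
    for contig, length in contig_lengths.items():
        arr = np.zeros(length)
        for start, end, value in cov.get(contig, ()):
            arr[max(start, 0) : min(end, length)] = value
        dense[contig] = arr
    return dense


def read_table(
    path: str | Path,
    required: Sequence[str] = (),
    index_col: str | None = None,
) -> pd.DataFrame:
    """Read a TSV with header, validating required columns.

    Comment lines starting with '#' are skipped; extra columns are
    preserved; numeric parsing is locale-independent (C locale decimal
    point, as pandas guarantees).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    provenance: Sequence[str] = (),
    index: bool = True,
) -> None:
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)
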