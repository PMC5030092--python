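"""In-silico restriction digestion and sequence GC skew.

DRIP-seq quantifies R-loops over the fragments produced by a restriction
enzyme cocktail, so the genomic intervals of the whole analysis are defined
here: every exact forward-strand match of each enzyme's recognition sequence
yields a cut, and consecutive cuts delimit a fragment.  The default cocktail
(BsrGI, EcoRI, HindIII, SspI, XbaI) consists of 6-bp palindromic cutters, so
a forward-strand search finds every site on either strand.

GC skew — the (G-C)/(G+C) strand asymmetry — is a sequence correlate of
R-loop formation (the displaced strand is stabilized when G-rich) and is
computed directly from sequence in sliding windows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "EnzymeSpec",
    "RestrictionSite",
    "FragmentInterval",
    "GcSkewTrack",
    "ENZYME_TABLE",
    "get_enzymes",
    "find_restriction_sites",
    "digest_to_fragments",
    "digest_genome",
    "gc_skew_profile",
]

_VALID_BASES = frozenset("ACGTN")


class ConfigurationError(ValueError):
    """Raised for invalid enzyme names or malformed enzyme definitions."""


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition sequence and cut offset.

    ``cut_offset`` is the 0-based position of the cut within the recognition
    sequence; a match starting at genome position ``p`` cuts at
    ``p + cut_offset``.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if not rec:
            raise ConfigurationError(f"enzyme {self.name!r}: empty recognition sequence")
        if not set(rec) <= frozenset("ACGT"):
            raise ConfigurationError(
                f"enzyme {self.name!r}: recognition must be over A/C/G/T, got {self.recognition!r}"
            )
        if not 0 <= self.cut_offset <= len(rec):
            raise ConfigurationError(
                f"enzyme {self.name!r}: cut_offset {self.cut_offset} outside recognition length {len(rec)}"
            )
        object.__setattr__(self, "recognition", rec)


#: The DRIP digestion cocktail with canonical cut conventions
#: (caret marks the cut: T^GTACA, G^AATTC, A^AGCTT, AAT^ATT, T^CTAGA).
#: All five recognition sequences are palindromic, so a forward-strand
#: search finds all sites.
ENZYME_TABLE: dict[str, EnzymeSpec] = {
    e.name: e
    for e in (
        EnzymeSpec("BsrGI", "TGTACA", 1),
        EnzymeSpec("EcoRI", "GAATTC", 1),
        EnzymeSpec("HindIII", "AAGCTT", 1),
        EnzymeSpec("SspI", "AATATT", 3),
        EnzymeSpec("XbaI", "TCTAGA", 1),
    )
}


def get_enzymes(names: Iterable[str]) -> list[EnzymeSpec]:
    """Resolve enzyme names against the built-in table (case-insensitive)."""
    lookup = {k.lower(): v for k, v in ENZYME_TABLE.items()}
    out = []
    for name in names:
        spec = lookup.get(name.lower())
        if spec is None:
            raise ConfigurationError(
                f"unknown enzyme {name!r}; known: {sorted(ENZYME_TABLE)}"
            )
        out.append(spec)
    return out


@dataclass(frozen=True)
class RestrictionSite:
    """An exact recognition-sequence match on the forward strand."""

    contig: str
    position: int  # 0-based start of the recognition match
    enzyme: str
    cut_position: int  # position + cut_offset


@dataclass(frozen=True)
class FragmentInterval:
    """A restriction fragment, 0-based half-open ``[start, end)``."""

    contig: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.id}: start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GcSkewTrack:
    """Windowed (G-C)/(G+C) values for one contig."""

    contig: str
    window: int
    step: int
    starts: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)


def _normalize_sequence(contig: str, sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"contig {contig!r}: unsupported characters {sorted(bad)}; "
            "only A/C/G/T/N are accepted (IUPAC ambiguity codes other than N are rejected)"
        )
    return seq


def find_restriction_sites(
    genome: Mapping[str, str], enzymes: Sequence[EnzymeSpec]
) -> list[RestrictionSite]:
    """Report every exact forward-strand recognition match, overlaps included.

    Matching requires exact base identity, so a recognition sequence spanning
    an ``N`` is never reported.  Results are sorted by (contig, position,
    enzyme name).
    """
    sites: list[RestrictionSite] = []
    for contig in sorted(genome):
        seq = _normalize_sequence(contig, genome[contig])
        for enz in enzymes:
            # lookahead regex reports overlapping matches
            pattern = re.compile(f"(?={re.escape(enz.recognition)})")
            for m in pattern.finditer(seq):
                pos = m.start()
                sites.append(
                    RestrictionSite(contig, pos, enz.name, pos + enz.cut_offset)
                )
    sites.sort(key=lambda s: (s.contig, s.position, s.enzyme))
    return sites


def digest_to_fragments(
    contig_lengths: Mapping[str, int], sites: Iterable[RestrictionSite]
) -> list[FragmentInterval]:
    """Tile each contig into fragments delimited by the sorted unique cut positions.

    Duplicate cut positions (e.g. two enzymes cutting at the same coordinate)
    collapse to a single boundary; cuts at 0 or at the contig end produce no
    zero-length fragment.  Fragments exactly tile ``[0, contig_length)``.
    """
    cuts_by_contig: dict[str, set[int]] = {c: set() for c in contig_lengths}
    for site in sites:
        if site.contig not in contig_lengths:
            raise ValueError(f"site on unknown contig {site.contig!r}")
        length = contig_lengths[site.contig]
        if not 0 <= site.cut_position <= length:
            raise ValueError(
                f"cut position {site.cut_position} out of bounds for contig "
                f"{site.contig!r} (length {length})"
            )
        cuts_by_contig[site.contig].add(site.cut_position)

    fragments: list[FragmentInterval] = []
    for contig in sorted(contig_lengths):
        length = contig_lengths[contig]
        if length <= 0:
            raise ValueError(f"contig {contig!r} has non-positive length {length}")
        boundaries = sorted({0, length} | cuts_by_contig[contig])
        for start, end in zip(boundaries[:-1], boundaries[1:]):
            if end > start:
                fragments.append(
                    FragmentInterval(contig, start, end, f"{contig}:{start}-{end}")
                )
    return fragments


def digest_genome(
    genome: Mapping[str, str],
    enzymes: Sequence[EnzymeSpec] | None = None,
    boundary: str = "cut",
) -> list[FragmentInterval]:
    """Digest a genome with an enzyme cocktail (default: the DRIP cocktail).

    ``boundary`` selects the fragment-boundary convention: ``"cut"`` places
    boundaries at the physical cut positions (recognition start + cut offset,
    the default, matching actual digestion), ``"site_start"`` at recognition
    starts.
    """
    if enzymes is None:
        enzymes = list(ENZYME_TABLE.values())
    if boundary not in ("cut", "site_start"):
        raise ConfigurationError(f"boundary must be 'cut' or 'site_start', got {boundary!r}")
    sites = find_restriction_sites(genome, enzymes)
    if boundary == "site_start":
        sites = [
            RestrictionSite(s.contig, s.position, s.enzyme, s.position) for s in sites
        ]
    lengths = {c: len(seq) for c, seq in genome.items()}
    return digest_to_fragments(lengths, sites)


def gc_skew_profile(
    sequence: str,
    window: int,
    step: int | None = None,
    contig: str = "seq",
) -> GcSkewTrack:
    """Windowed GC skew (G-C)/(G+C); windows with no G or C carry value 0.

    One value per window start at ``0, step, 2*step, ...`` while the full
    window fits in the sequence.  ``N`` bases count toward neither G nor C.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = window if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    seq = _normalize_sequence(contig, sequence)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    g_cum = np.concatenate([[0], np.cumsum(arr == ord("G"))])
    c_cum = np.concatenate([[0], np.cumsum(arr == ord("C"))])
    starts = np.arange(0, len(seq) - window + 1, step, dtype=np.int64)
    g = g_cum[starts + window] - g_cum[starts]
    c = c_cum[starts + window] - c_cum[starts]
    denom = g + c
    with np.errstate(invalid="ignore"):
        values = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    return GcSkewTrack(contig=contig, window=window, step=step, starts=starts, values=values)
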