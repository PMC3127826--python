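"""Promoter sequence features: motif scanning, McrBC recognition sites,
pairwise identity.

McrBC requires two methylated half-sites of the form purine-C separated by
40-3000 bases; the half-site enumeration and the pair-eligibility window
here are the sequence-level counterparts of that requirement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from Bio.Align import PairwiseAligner
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .coords import ReferenceRegion, index_to_atg

MIN_PAIR_SEPARATION = 40
MAX_PAIR_SEPARATION = 3000

#: top-strand purine-C half-site dinucleotides
_FORWARD_HALFSITES = ("AC", "GC")
#: bottom-strand half-sites as they read on the top strand (revcomp of AC/GC)
_REVERSE_HALFSITES = ("GT", "GC")


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based offset, or ATG-relative when scanned on a region
    strand: str  # "+" or "-"
    match: str


@dataclass(frozen=True)
class HalfSite:
    position: int
    strand: str


def expand_iupac(code: str) -> set[str]:
    """Set of concrete bases an IUPAC code admits."""
    try:
        return set(ambiguous_dna_values[code.upper()])
    except KeyError:
        raise ValueError(f"not an IUPAC DNA code: {code!r}") from None


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _iupac_pattern(motif: str) -> re.Pattern:
    parts = []
    for c in motif.upper():
        bases = sorted(expand_iupac(c))
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motif(target: str | ReferenceRegion, motif: str,
               both_strands: bool = True) -> list[MotifHit]:
    """Find all (IUPAC-expanded) occurrences of ``motif``.

    Reverse-strand hits are reported at the forward-strand start of the
    matched window.  When ``target`` is a :class:`ReferenceRegion`,
    positions are ATG-relative.
    """
    if not motif:
        raise ValueError("empty motif")
    region = target if isinstance(target, ReferenceRegion) else None
    seq = region.sequence if region else target.upper()

    hits: list[MotifHit] = []
    for m in _iupac_pattern(motif).finditer(seq):
        hits.append(MotifHit(m.start(), "+", m.group(1)))
    if both_strands:
        for m in _iupac_pattern(reverse_complement(motif)).finditer(seq):
            hits.append(MotifHit(m.start(), "-", m.group(1)))
    hits.sort(key=lambda h: (h.position, h.strand))
    if region:
        hits = [MotifHit(index_to_atg(h.position, region), h.strand, h.match)
                for h in hits]
    return hits


def count_mcrbc_halfsites(seq: str, both_strands: bool = False) -> list[HalfSite]:
    """Enumerate purine-C McrBC half-sites; N never matches.

    Positions are 0-based offsets of the dinucleotide start on the top
    strand (bottom-strand sites are reported at the same top-strand offset
    with strand ``"-"``).
    """
    seq = seq.upper()
    sites: list[HalfSite] = []
    for i in range(len(seq) - 1):
        di = seq[i : i + 2]
        if di in _FORWARD_HALFSITES:
            sites.append(HalfSite(i, "+"))
        if both_strands and di in _REVERSE_HALFSITES:
            sites.append(HalfSite(i, "-"))
    return sites


def enumerate_mcrbc_pairs(positions: Sequence[int],
                          min_sep: int = MIN_PAIR_SEPARATION,
                          max_sep: int = MAX_PAIR_SEPARATION) -> list[tuple[int, int]]:
    """All position pairs whose start-to-start separation is in [min_sep, max_sep]."""
    pos = sorted(positions)
    return [(a, b) for a, b in combinations(pos, 2) if min_sep <= b - a <= max_sep]


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(seq_a: str, seq_b: str, mode: str = "global") -> float:
    """Percent identity between two sequences.

    ``global`` aligns (match 1, mismatch -1, gap open -2, extend -1) and
    reports identical columns / alignment columns x 100.  ``ungapped``
    requires equal lengths and is a plain positional comparison.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if mode == "ungapped":
        if len(seq_a) != len(seq_b):
            raise ValueError("ungapped identity requires equal lengths")
        matches = sum(a == b for a, b in zip(seq_a, seq_b))
        return 100.0 * matches / len(seq_a)
    if mode != "global":
        raise ValueError(f"unknown mode {mode!r}")
    alignment = _global_aligner().align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length
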