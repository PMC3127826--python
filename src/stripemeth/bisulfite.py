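"""Amplicon bisulfite Sanger-clone analysis.

Clones are aligned to the unconverted reference fragment with an aligner
that treats reference-C vs clone-T (expected conversion) and reference-C
vs clone-C (methylation) as free matches, so conversion state cannot
distort the alignment.  Calls are made on the forward (bisulfite top)
strand only.  Ambiguous calls (gaps, unexpected bases) are excluded from
all percentage denominators rather than counted as unmethylated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .coords import AmpliconFragment, ReferenceRegion, atg_to_index, index_to_atg
from .features import expand_iupac, reverse_complement

CONTEXTS = ("CG", "CHG", "CHH")

# call codes in the clone x position matrix
METHYLATED = 1
UNMETHYLATED = 0
AMBIGUOUS = -1


def classify_context_at(seq: str, i: int) -> str:
    """Context of the cytosine at 0-based index ``i`` of ``seq``.

    CG needs one readable downstream base; CHG/CHH need two.  Any N or a
    truncated downstream window gives ``unknown``.
    """
    if seq[i] != "C":
        raise ValueError(f"base at index {i} is {seq[i]!r}, not C")
    if i + 1 >= len(seq):
        return "unknown"
    b1 = seq[i + 1]
    if b1 == "G":
        return "CG"
    if b1 not in "ACT":
        return "unknown"
    if i + 2 >= len(seq):
        return "unknown"
    b2 = seq[i + 2]
    if b2 == "G":
        return "CHG"
    if b2 in "ACT":
        return "CHH"
    return "unknown"


def classify_context(region: ReferenceRegion, pos: int) -> str:
    """Context of the cytosine at ATG-relative position ``pos``."""
    return classify_context_at(region.sequence, atg_to_index(pos, region))


def convert_in_silico(sequence: str, methylated_positions: Iterable[int] = ()) -> str:
    """Bisulfite-convert a fragment: every unmethylated C reads as T."""
    sequence = sequence.upper()
    meth = set(methylated_positions)
    for p in meth:
        if not 0 <= p < len(sequence) or sequence[p] != "C":
            raise ValueError(f"methylated position {p} is not a C")
    return "".join(
        "C" if (b == "C" and i in meth) else ("T" if b == "C" else b)
        for i, b in enumerate(sequence)
    )


def call_methylation(ref_base: str, clone_base: str) -> int:
    """Score one reference cytosine against the aligned clone base."""
    if ref_base != "C":
        raise ValueError(f"reference base is {ref_base!r}, not C")
    if clone_base == "C":
        return METHYLATED
    if clone_base == "T":
        return UNMETHYLATED
    return AMBIGUOUS


@dataclass
class AlignerConfig:
    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    length_tolerance: float = 0.20  # clone length within +/-20% of reference
    identity_floor: float = 0.80  # on non-C reference positions


def _bisulfite_aligner(cfg: AlignerConfig) -> PairwiseAligner:
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            matrix[a, b] = cfg.match if a == b else cfg.mismatch
        matrix[a, "N"] = 0.0
        matrix["N", a] = 0.0
    # conversion-neutral scoring: reference C aligns freely to clone C or T
    matrix["C", "T"] = cfg.match
    matrix["C", "C"] = cfg.match
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = cfg.gap_open
    aligner.extend_gap_score = cfg.gap_extend
    return aligner


@dataclass
class CloneAlignment:
    ok: bool
    reason: str
    mapped: str  # clone base per reference position; '-' for deletions
    identity: float  # on non-C reference positions


def align_clone(clone: str, reference: str,
                cfg: AlignerConfig | None = None) -> CloneAlignment:
    """Globally align one clone to the unconverted reference fragment.

    Returns the clone base over every reference position ('-' where the
    clone has a deletion; clone insertions are dropped), plus an identity
    measured only on non-C reference positions, where bisulfite chemistry
    leaves no freedom.
    """
    cfg = cfg or AlignerConfig()
    if not clone:
        return CloneAlignment(False, "empty clone", "", 0.0)
    clone = clone.upper()
    lo = len(reference) * (1 - cfg.length_tolerance)
    hi = len(reference) * (1 + cfg.length_tolerance)
    if not lo <= len(clone) <= hi:
        return CloneAlignment(
            False,
            f"clone length {len(clone)} outside {lo:.0f}..{hi:.0f}",
            "", 0.0,
        )
    alignment = _bisulfite_aligner(cfg).align(reference, clone)[0]
    aligned_ref, aligned_clone = str(alignment[0]), str(alignment[1])
    mapped = []
    for r, c in zip(aligned_ref, aligned_clone):
        if r == "-":
            continue  # insertion in clone
        mapped.append(c)
    mapped_str = "".join(mapped)
    non_c = [(r, c) for r, c in zip(reference, mapped_str) if r != "C"]
    identity = (sum(r == c for r, c in non_c) / len(non_c)) if non_c else 1.0
    if identity < cfg.identity_floor:
        return CloneAlignment(
            False,
            f"identity {identity:.2f} below floor {cfg.identity_floor:.2f}",
            mapped_str, identity,
        )
    return CloneAlignment(True, "", mapped_str, identity)


@dataclass
class BisulfiteCloneSet:
    """Aligned, called clones for one sample x fragment."""

    sample: str
    reference: str  # unconverted fragment sequence
    c_positions: np.ndarray  # fragment-local 0-based indices of reference Cs
    contexts: list[str]  # context per C position
    clone_names: list[str]
    call_matrix: np.ndarray  # n_clones x n_c_positions, codes above
    fragment: AmpliconFragment | None = None
    atg_positions: np.ndarray | None = None  # ATG-relative C positions
    rejected: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_clones(self) -> int:
        return self.call_matrix.shape[0]

    def counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(methylated, unmethylated, ambiguous) counts per position."""
        m = (self.call_matrix == METHYLATED).sum(axis=0)
        u = (self.call_matrix == UNMETHYLATED).sum(axis=0)
        a = (self.call_matrix == AMBIGUOUS).sum(axis=0)
        return m, u, a


def analyze_clones(sample: str,
                   clones: Sequence[tuple[str, str]],
                   reference: str | ReferenceRegion,
                   fragment: AmpliconFragment | None = None,
                   cfg: AlignerConfig | None = None) -> BisulfiteCloneSet:
    """Align clone sequences and build the per-cytosine call matrix.

    ``reference`` may be a plain fragment sequence, or a full
    :class:`ReferenceRegion` together with ``fragment`` (in which case
    contexts use region sequence beyond the fragment boundary and
    positions are also reported ATG-relative).
    """
    cfg = cfg or AlignerConfig()
    region = reference if isinstance(reference, ReferenceRegion) else None
    if region is not None:
        if fragment is None:
            raise ValueError("fragment required when passing a ReferenceRegion")
        ref_seq = fragment.sequence(region)
        frag_start_idx = atg_to_index(fragment.start, region)
    else:
        ref_seq = reference.upper()
        frag_start_idx = 0

    c_positions = np.array([i for i, b in enumerate(ref_seq) if b == "C"], dtype=int)
    if c_positions.size == 0:
        warnings.warn(f"fragment for sample {sample!r} contains no cytosines")
    if region is not None:
        contexts = [classify_context_at(region.sequence, frag_start_idx + int(i))
                    for i in c_positions]
        atg_positions = np.array(
            [index_to_atg(frag_start_idx + int(i), region) for i in c_positions],
            dtype=int,
        )
    else:
        contexts = [classify_context_at(ref_seq, int(i)) for i in c_positions]
        atg_positions = None

    names, rows, rejected = [], [], []
    for name, seq in clones:
        aln = align_clone(seq, ref_seq, cfg)
        if not aln.ok:
            rejected.append((name, aln.reason))
            continue
        rows.append([call_methylation("C", aln.mapped[i]) for i in c_positions])
        names.append(name)
    matrix = (np.array(rows, dtype=np.int8) if rows
              else np.empty((0, c_positions.size), dtype=np.int8))
    return BisulfiteCloneSet(
        sample=sample, reference=ref_seq, c_positions=c_positions,
        contexts=contexts, clone_names=names, call_matrix=matrix,
        fragment=fragment, atg_positions=atg_positions, rejected=rejected,
    )


@dataclass
class RegionMethylationSummary:
    sample: str
    positions: np.ndarray  # fragment-local C indices
    atg_positions: np.ndarray | None
    contexts: list[str]
    per_position_percent: np.ndarray  # NaN where no unambiguous calls
    per_position_calls: np.ndarray  # unambiguous calls per position
    per_context_percent: dict[str, float]
    per_context_calls: dict[str, int]
    per_clone_percent: list[float]
    clone_names: list[str]
    region_percent: float
    region_calls: int


def summarize_region(clone_set: BisulfiteCloneSet) -> RegionMethylationSummary:
    """Per-position, per-context, per-clone and region-wide percent methylation."""
    if clone_set.n_clones == 0:
        raise ValueError("no clones to summarize")
    m, u, a = clone_set.counts()
    calls = m + u
    if calls.sum() == 0:
        raise ValueError("no unambiguous calls in clone set")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_pos = np.where(calls > 0, 100.0 * m / np.maximum(calls, 1), np.nan)

    ctx_arr = np.array(clone_set.contexts)
    per_ctx_pct: dict[str, float] = {}
    per_ctx_calls: dict[str, int] = {}
    for ctx in CONTEXTS:
        mask = ctx_arr == ctx
        n_calls = int(calls[mask].sum())
        per_ctx_calls[ctx] = n_calls
        per_ctx_pct[ctx] = (100.0 * m[mask].sum() / n_calls) if n_calls else float("nan")

    per_clone = []
    for row in clone_set.call_matrix:
        n = int((row != AMBIGUOUS).sum())
        per_clone.append(100.0 * float((row == METHYLATED).sum()) / n if n else float("nan"))

    return RegionMethylationSummary(
        sample=clone_set.sample,
        positions=clone_set.c_positions,
        atg_positions=clone_set.atg_positions,
        contexts=clone_set.contexts,
        per_position_percent=per_pos,
        per_position_calls=calls,
        per_context_percent=per_ctx_pct,
        per_context_calls=per_ctx_calls,
        per_clone_percent=per_clone,
        clone_names=clone_set.clone_names,
        region_percent=100.0 * float(m.sum()) / float(calls.sum()),
        region_calls=int(calls.sum()),
    )


@dataclass
class StripeComparison:
    region_difference: float  # green minus red, percentage points
    mean_position_difference: float
    per_position_difference: np.ndarray
    fraction_green_higher: float
    n_positions_compared: int
    green_percent: float
    red_percent: float


def compare_stripes(green: RegionMethylationSummary,
                    red: RegionMethylationSummary) -> StripeComparison:
    """Green-vs-red comparison over identical fragment positions.

    The strictly-higher fraction is computed over positions with
    unambiguous calls in both sets; ties stay in the denominator.
    """
    if not np.array_equal(green.positions, red.positions):
        raise ValueError("summaries cover different positions")
    diff = green.per_position_percent - red.per_position_percent
    both = ~np.isnan(green.per_position_percent) & ~np.isnan(red.per_position_percent)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no positions with calls in both summaries")
    higher = int((diff[both] > 0).sum())
    return StripeComparison(
        region_difference=green.region_percent - red.region_percent,
        mean_position_difference=float(np.nanmean(diff[both])),
        per_position_difference=diff,
        fraction_green_higher=100.0 * higher / n,
        n_positions_compared=n,
        green_percent=green.region_percent,
        red_percent=red.region_percent,
    )


@dataclass
class PrimerBiasResult:
    unbiased: bool
    offset: int  # fragment-local offset of the primer footprint
    biased_positions: list[int]  # fragment-local reference-C positions


def _compatible(primer_char: str, ref_char: str) -> bool:
    allowed = expand_iupac(primer_char)
    if ref_char == "C":
        # post-conversion the template reads T (unmethylated) or C (methylated)
        return bool(allowed & {"C", "T"})
    if ref_char == "N":
        return True
    return ref_char in allowed


def check_primer_bias(primer: str, reference: str, orientation: str) -> PrimerBiasResult:
    """Does a bisulfite PCR primer amplify methylated and unmethylated templates alike?

    The primer is mapped onto the top strand (reverse primers via reverse
    complement, which turns the R-degeneracy rule into the same C/T rule).
    It is unbiased iff every covered reference C admits both C and T.
    """
    primer = primer.upper()
    reference = reference.upper()
    if orientation not in ("forward", "reverse"):
        raise ValueError("orientation must be 'forward' or 'reverse'")
    probe = primer if orientation == "forward" else reverse_complement(primer)

    hit = None
    for off in range(len(reference) - len(probe) + 1):
        if all(_compatible(p, reference[off + k]) for k, p in enumerate(probe)):
            hit = off
            break
    if hit is None:
        raise ValueError(f"{orientation} primer not locatable on fragment")
    biased = []
    for k, p in enumerate(probe):
        if reference[hit + k] == "C" and not {"C", "T"} <= expand_iupac(p):
            biased.append(hit + k)
    return PrimerBiasResult(unbiased=not biased, offset=hit, biased_positions=biased)


@dataclass
class MotifMethylation:
    motif_start: int  # fragment-local
    motif_end: int  # inclusive
    status: str  # "scored", "no scorable cytosines", "skipped: ..."
    inside_percent: float
    flank_percent: float
    n_inside_cs: int
    n_flank_cs: int


def motif_methylation(clone_set: BisulfiteCloneSet,
                      motif_spans: Sequence[tuple[int, int]],
                      flank: int = 10) -> list[MotifMethylation]:
    """Percent methylation inside each motif occurrence and in +/-``flank`` bases.

    Spans are fragment-local inclusive (start, end).  Occurrences falling
    partly outside the analyzed fragment are skipped with a note.
    """
    m, u, _ = clone_set.counts()
    results = []
    for start, end in motif_spans:
        if start < 0 or end >= len(clone_set.reference) or start > end:
            results.append(MotifMethylation(start, end, "skipped: outside fragment",
                                            float("nan"), float("nan"), 0, 0))
            continue
        inside = (clone_set.c_positions >= start) & (clone_set.c_positions <= end)
        lo, hi = max(0, start - flank), min(len(clone_set.reference) - 1, end + flank)
        flank_mask = (((clone_set.c_positions >= lo) & (clone_set.c_positions < start))
                      | ((clone_set.c_positions > end) & (clone_set.c_positions <= hi)))

        def _pct(mask):
            calls = int(m[mask].sum() + u[mask].sum())
            return (100.0 * m[mask].sum() / calls if calls else float("nan")), calls

        inside_pct, n_in = _pct(inside)
        flank_pct, n_fl = _pct(flank_mask)
        status = "scored" if inside.any() else "no scorable cytosines"
        results.append(MotifMethylation(start, end, status, inside_pct, flank_pct,
                                        int(inside.sum()), int(flank_mask.sum())))
    return results
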