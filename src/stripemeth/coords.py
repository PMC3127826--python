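"""Reference regions and the ATG-relative coordinate system.

Positions are reported relative to the A of the translation-start ATG,
with no position zero: ``..., -2, -1, +1, +2, ...`` and ``+1`` is the A
itself.  Internally everything is stored 0-based; the conversion helpers
here are the only place the two systems meet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_DNA = set("ACGTN")
_IUPAC = set("ACGTRYSWKMBDHVN")


class CoordinateError(ValueError):
    """Base class for coordinate problems."""


class InvalidCoordinateError(CoordinateError):
    """Raised for the non-existent position 0."""


class BoundsError(CoordinateError):
    """Raised when a coordinate falls outside the reference sequence."""


@dataclass(frozen=True)
class ReferenceRegion:
    """A promoter/gene reference with an ATG anchor.

    Parameters
    ----------
    name : str
        Region label (e.g. an accession).
    sequence : str
        Uppercase DNA over ``{A, C, G, T, N}``.
    atg_offset : int
        0-based index in ``sequence`` of the A of the start codon.
    annotations : list of (label, start, end)
        Optional features in ATG-relative inclusive coordinates.
    """

    name: str
    sequence: str
    atg_offset: int
    annotations: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(f"non-DNA characters in reference: {sorted(bad)}")
        if not 0 <= self.atg_offset < len(seq):
            raise BoundsError(
                f"atg_offset {self.atg_offset} outside sequence of length {len(seq)}"
            )
        if self.atg_offset + 3 <= len(seq):
            codon = seq[self.atg_offset : self.atg_offset + 3]
            if codon != "ATG":
                raise ValueError(
                    f"sequence at atg_offset is {codon!r}, expected 'ATG'"
                )
        object.__setattr__(self, "annotations", tuple(self.annotations))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def min_pos(self) -> int:
        """Smallest valid ATG-relative position."""
        return -self.atg_offset if self.atg_offset > 0 else 1

    @property
    def max_pos(self) -> int:
        """Largest valid ATG-relative position."""
        return len(self.sequence) - self.atg_offset


def atg_to_index(pos: int, region: ReferenceRegion) -> int:
    """Convert an ATG-relative position to a 0-based sequence index."""
    if pos == 0:
        raise InvalidCoordinateError("ATG-relative coordinates have no position 0")
    idx = region.atg_offset + pos - 1 if pos > 0 else region.atg_offset + pos
    if not 0 <= idx < len(region.sequence):
        raise BoundsError(
            f"position {pos:+d} maps outside reference '{region.name}' "
            f"(length {len(region.sequence)}, ATG at index {region.atg_offset})"
        )
    return idx


def index_to_atg(idx: int, region: ReferenceRegion) -> int:
    """Inverse of :func:`atg_to_index`."""
    if not 0 <= idx < len(region.sequence):
        raise BoundsError(f"index {idx} outside sequence")
    rel = idx - region.atg_offset
    return rel + 1 if rel >= 0 else rel


def span_length(start: int, end: int) -> int:
    """Inclusive number of positions in ``start..end``, skipping the absent 0."""
    if start == 0 or end == 0:
        raise InvalidCoordinateError("ATG-relative coordinates have no position 0")
    if start > end:
        raise CoordinateError(f"start {start:+d} > end {end:+d}")
    n = end - start + 1
    if start < 0 < end:
        n -= 1
    return n


def extract_fragment(region: ReferenceRegion, start: int, end: int) -> str:
    """Return the reference bases covering ATG-relative ``start..end`` inclusive."""
    i = atg_to_index(start, region)
    j = atg_to_index(end, region)
    if i > j:
        raise CoordinateError(f"start {start:+d} > end {end:+d}")
    return region.sequence[i : j + 1]


@dataclass(frozen=True)
class AmpliconFragment:
    """A PCR amplicon given by its inclusive ATG-relative boundaries."""

    start: int
    end: int
    forward_primer: str = ""
    reverse_primer: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.start == 0 or self.end == 0:
            raise InvalidCoordinateError("fragment endpoints cannot be 0")
        if self.start >= self.end:
            raise CoordinateError(
                f"fragment start {self.start:+d} must precede end {self.end:+d}"
            )
        for label, primer in (("forward", self.forward_primer),
                              ("reverse", self.reverse_primer)):
            bad = set(primer.upper()) - _IUPAC
            if bad:
                raise ValueError(f"{label} primer has non-IUPAC characters {sorted(bad)}")
        if self.forward_primer and self.reverse_primer:
            if self.length <= len(self.forward_primer) + len(self.reverse_primer):
                raise ValueError(
                    "fragment shorter than its primers combined: "
                    f"{self.length} <= {len(self.forward_primer)} + {len(self.reverse_primer)}"
                )
        if not self.name:
            object.__setattr__(self, "name", f"{self.start}..{self.end}")

    @property
    def length(self) -> int:
        return span_length(self.start, self.end)

    def sequence(self, region: ReferenceRegion) -> str:
        return extract_fragment(region, self.start, self.end)
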