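"""Synthetic references, methylation mosaics, bisulfite clones, McrBC
molecule pools and qPCR Ct values.

Every generator takes an explicit seed and is deterministic given it.
The bisulfite clone generator emits raw sequences (plus the drawn truth)
so the downstream alignment/calling path is exercised for real rather
than being fed its own answers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bisulfite import classify_context_at
from .coords import (AmpliconFragment, ReferenceRegion, atg_to_index,
                     index_to_atg)
from .features import MIN_PAIR_SEPARATION, MAX_PAIR_SEPARATION, count_mcrbc_halfsites
from .io import CT_COLUMNS, NO_AMPLIFICATION

_BASES = np.array(list("ACGT"))


def gen_reference(length: int, gc_fraction: float = 0.40,
                  embedded_motifs: Sequence[tuple[str, int]] = (),
                  seed: int | None = None, atg_offset: int | None = None,
                  name: str = "synthetic") -> ReferenceRegion:
    """Random reference with an ATG anchor and verbatim embedded motifs.

    ``embedded_motifs`` is a list of (motif, ATG-relative start).  The
    default ATG sits 150 bases from the 3' end so most of the region is
    promoter-like.
    """
    if atg_offset is None:
        atg_offset = max(0, length - 150)
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    seq = rng.choice(_BASES, size=length, p=p)
    if atg_offset + 3 <= length:
        seq[atg_offset : atg_offset + 3] = list("ATG")

    placed: list[tuple[int, int]] = []
    for motif, pos in embedded_motifs:
        if pos == 0:
            raise ValueError("motif position 0 does not exist")
        start = atg_offset + pos - 1 if pos > 0 else atg_offset + pos
        end = start + len(motif)
        if start < 0 or end > length:
            raise ValueError(f"motif {motif!r} at {pos:+d} outside reference")
        for s, e in placed:
            if start < e and s < end:
                raise ValueError(f"motif {motif!r} at {pos:+d} overlaps another motif")
        placed.append((start, end))
        seq[start:end] = list(motif.upper())
    return ReferenceRegion(name=name, sequence="".join(seq), atg_offset=atg_offset)


@dataclass
class MethylationProfile:
    """Per-cytosine methylation probability truth over a reference's forward strand."""

    region: ReferenceRegion
    c_indices: np.ndarray  # 0-based indices of every forward-strand C
    contexts: np.ndarray  # context label per C
    p: np.ndarray  # probability per C, in [0, 1]

    def __post_init__(self) -> None:
        if not (len(self.c_indices) == len(self.contexts) == len(self.p)):
            raise ValueError("profile arrays must have equal length")
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("methylation probabilities must lie in [0, 1]")

    @property
    def atg_positions(self) -> np.ndarray:
        return np.array([index_to_atg(int(i), self.region) for i in self.c_indices])

    def p_at_index(self, idx: int) -> float:
        where = np.searchsorted(self.c_indices, idx)
        if where >= len(self.c_indices) or self.c_indices[where] != idx:
            raise KeyError(f"index {idx} is not a cytosine position")
        return float(self.p[where])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.atg_positions,
            "context": self.contexts,
            "p": self.p,
        })


@dataclass
class StripePair:
    green: MethylationProfile
    red: MethylationProfile
    delta: np.ndarray  # green minus red, per C position

    def __post_init__(self) -> None:
        expected = np.clip(self.red.p + self.delta, 0.0, 1.0)
        if not np.allclose(self.green.p, expected):
            raise ValueError("green profile must equal clamp(red + delta)")


def gen_profile(region: ReferenceRegion,
                base_rates: Mapping[str, float],
                blocks: Sequence[tuple[int, int, object]] = (),
                stripe_delta: float = 0.0) -> StripePair:
    """Build red/green truth profiles from per-context base rates.

    ``blocks`` are (start, end, value) in ATG-relative inclusive
    coordinates; a float value overrides the probability inside the block,
    a ``{"multiplier": m}`` mapping scales it.  Green equals red plus
    ``stripe_delta`` clamped to [0, 1].
    """
    for ctx, rate in base_rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"base rate for {ctx} outside [0, 1]: {rate}")
    seq = region.sequence
    c_indices = np.array([i for i, b in enumerate(seq) if b == "C"], dtype=int)
    contexts = np.array([classify_context_at(seq, int(i)) for i in c_indices])
    p_red = np.array([base_rates.get(ctx, 0.0) for ctx in contexts], dtype=float)

    resolved: dict[int, float] = {}
    for start, end, value in blocks:
        i0, i1 = atg_to_index(start, region), atg_to_index(end, region)
        mask = (c_indices >= i0) & (c_indices <= i1)
        if isinstance(value, Mapping):
            new = np.clip(p_red * float(value["multiplier"]), 0.0, 1.0)
        else:
            new = np.full_like(p_red, float(value))
        for j in np.flatnonzero(mask):
            if j in resolved and not math.isclose(resolved[j], new[j]):
                pos = index_to_atg(int(c_indices[j]), region)
                raise ValueError(f"conflicting block overrides at position {pos:+d}")
            resolved[j] = float(new[j])
            p_red[j] = new[j]
    p_red = np.clip(p_red, 0.0, 1.0)

    delta = np.full_like(p_red, float(stripe_delta))
    p_green = np.clip(p_red + delta, 0.0, 1.0)
    red = MethylationProfile(region, c_indices, contexts, p_red)
    green = MethylationProfile(region, c_indices, contexts, p_green)
    return StripePair(green=green, red=red, delta=delta)


@dataclass
class SimulatedClones:
    """Raw bisulfite clone sequences plus the drawn per-clone truth."""

    sample: str
    fragment: AmpliconFragment
    reference: str  # unconverted fragment sequence
    clones: list[tuple[str, str]]  # (name, sequence)
    c_positions: np.ndarray  # fragment-local indices of reference Cs
    truth: np.ndarray  # n_clones x n_cs booleans: methylated at draw time
    vacuous: bool = False  # fragment contained no cytosines


def gen_bisulfite_clones(profile: MethylationProfile, fragment: AmpliconFragment,
                         n_clones: int, conversion_efficiency: float = 0.995,
                         seq_error_rate: float = 0.001, seed: int | None = None,
                         sample: str = "sample") -> SimulatedClones:
    """Draw bisulfite-converted clone sequences from a truth profile.

    Each clone's cytosines are methylated independently with their profile
    probability; unmethylated Cs convert to T with ``conversion_efficiency``;
    substitution noise hits every base independently at ``seq_error_rate``.
    """
    if n_clones < 1:
        raise ValueError("need at least one clone")
    for label, r in (("conversion_efficiency", conversion_efficiency),
                     ("seq_error_rate", seq_error_rate)):
        if not 0 <= r <= 1:
            raise ValueError(f"{label} outside [0, 1]: {r}")
    rng = np.random.default_rng(seed)
    region = profile.region
    frag_seq = fragment.sequence(region)
    i0 = atg_to_index(fragment.start, region)
    c_local = np.array([i for i, b in enumerate(frag_seq) if b == "C"], dtype=int)
    vacuous = c_local.size == 0
    if vacuous:
        warnings.warn(f"fragment {fragment.name} contains no cytosines")
    p = np.array([profile.p_at_index(i0 + int(i)) for i in c_local])

    clones = []
    truth = np.zeros((n_clones, c_local.size), dtype=bool)
    base_arr = np.array(list(frag_seq))
    for k in range(n_clones):
        meth = rng.random(c_local.size) < p
        truth[k] = meth
        seq = base_arr.copy()
        converts = rng.random(c_local.size) < conversion_efficiency
        seq[c_local[~meth & converts]] = "T"
        if seq_error_rate > 0:
            errs = np.flatnonzero(rng.random(len(seq)) < seq_error_rate)
            for e in errs:
                others = [b for b in "ACGT" if b != seq[e]]
                seq[e] = others[rng.integers(3)]
        clones.append((f"{sample}|clone_{k + 1:03d}", "".join(seq)))
    return SimulatedClones(sample=sample, fragment=fragment, reference=frag_seq,
                           clones=clones, c_positions=c_local, truth=truth,
                           vacuous=vacuous)


@dataclass
class MoleculePool:
    """Methylation states of template molecules at McrBC half-site positions."""

    halfsite_positions: np.ndarray  # 0-based top-strand positions, sorted
    states: np.ndarray  # n_molecules x n_halfsites booleans

    def __post_init__(self) -> None:
        if self.states.ndim != 2 or self.states.shape[1] != len(self.halfsite_positions):
            raise ValueError("states must be n_molecules x n_halfsites")

    @property
    def n_molecules(self) -> int:
        return self.states.shape[0]


def gen_molecule_pool(profile: MethylationProfile, n_molecules: int,
                      seed: int | None = None, clonal: bool = False) -> MoleculePool:
    """Draw per-molecule methylation states at every forward McrBC half-site.

    With ``clonal=True`` a single uniform draw per molecule is compared
    against every site's probability, modelling cell-lineage mosaicism: a
    constant-probability block is then methylated all-or-none per molecule.
    """
    if n_molecules < 1:
        raise ValueError("need at least one molecule")
    rng = np.random.default_rng(seed)
    sites = count_mcrbc_halfsites(profile.region.sequence, both_strands=False)
    positions = np.array([s.position for s in sites], dtype=int)
    # the methylatable C of a Pu-C half-site is the second base
    p = np.array([profile.p_at_index(int(pos) + 1) for pos in positions])
    if clonal:
        u = rng.random((n_molecules, 1))
        states = u < p[None, :]
    else:
        states = rng.random((n_molecules, p.size)) < p[None, :]
    return MoleculePool(halfsite_positions=positions, states=states)


def digest_pool(pool: MoleculePool, amplicon: tuple[int, int],
                min_sep: int = MIN_PAIR_SEPARATION,
                max_sep: int = MAX_PAIR_SEPARATION) -> np.ndarray:
    """Boolean per molecule: destroyed by McrBC for the given amplicon.

    A molecule is cut (non-amplifiable) iff it carries two methylated
    half-sites separated by ``min_sep..max_sep`` bases whose span
    intersects the amplicon interval (0-based, inclusive).
    """
    amp_start, amp_end = amplicon
    pos = pool.halfsite_positions
    cut = np.zeros(pool.n_molecules, dtype=bool)
    for k in range(pool.n_molecules):
        m = pos[pool.states[k]]
        if m.size < 2:
            continue
        a = m[m <= amp_end]
        if a.size == 0:
            continue
        lo = np.maximum(a + min_sep, amp_start)
        hi = a + max_sep
        i_lo = np.searchsorted(m, lo, side="left")
        i_hi = np.searchsorted(m, hi, side="right")
        if (i_hi > i_lo).any():
            cut[k] = True
    return cut


def non_amplifiable_fraction(pool: MoleculePool, region: ReferenceRegion,
                             fragment: AmpliconFragment, **kw) -> float:
    amp = (atg_to_index(fragment.start, region), atg_to_index(fragment.end, region))
    return float(digest_pool(pool, amp, **kw).mean())


def simulate_mcrbc_qpcr(pool: MoleculePool, region: ReferenceRegion,
                        fragment: AmpliconFragment, efficiency: float = 2.0,
                        ct_at_full_template: float = 24.0, noise_sd: float = 0.15,
                        n_replicates: int = 3, n_digestions: int = 2,
                        seed: int | None = None,
                        sample: str = "sample") -> pd.DataFrame:
    """Ct table (mcrbc + mock rows) for one sample x fragment.

    Mock Ct is the full-template Ct plus noise; McrBC Ct is shifted by
    -log_E(surviving fraction).  A fully digested pool yields the
    no-amplification sentinel on the McrBC side.
    """
    if not 1 < efficiency <= 2:
        raise ValueError(f"efficiency must be in (1, 2]: {efficiency}")
    if n_replicates < 1 or n_digestions < 1:
        raise ValueError("need at least one replicate and digestion")
    amp = (atg_to_index(fragment.start, region), atg_to_index(fragment.end, region))
    in_span = ((pool.halfsite_positions >= amp[0] - MAX_PAIR_SEPARATION)
               & (pool.halfsite_positions <= amp[1] + MAX_PAIR_SEPARATION))
    if int(in_span.sum()) < 2:
        warnings.warn(
            f"fragment {fragment.name}: fewer than 2 half-sites in reach; "
            "digestion impossible, estimator will read ~0%"
        )
    surviving = 1.0 - digest_pool(pool, amp).mean()
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(1, n_digestions + 1):
        for r in range(1, n_replicates + 1):
            rows.append((sample, fragment.name, "mock", d, r,
                         ct_at_full_template + rng.normal(0.0, noise_sd)))
        for r in range(1, n_replicates + 1):
            if surviving <= 0.0:
                ct = NO_AMPLIFICATION
            else:
                shift = -math.log(surviving) / math.log(efficiency)
                ct = ct_at_full_template + shift + rng.normal(0.0, noise_sd)
            rows.append((sample, fragment.name, "mcrbc", d, r, ct))
    return pd.DataFrame(rows, columns=CT_COLUMNS)
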