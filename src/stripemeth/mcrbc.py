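"""Percent-methylation estimation from McrBC vs mock qPCR.

The estimator is %M = 100 x (1 - E^-(Ct_McrBC - Ct_mock)): the fraction of
template copies destroyed by McrBC, inferred from the delta-Ct at
amplification efficiency E.  Negative raw values (McrBC side amplifying
earlier than mock) are clamped to 0 and flagged; very late or erratic
McrBC-side amplification marks the estimate low-template and withholds
the value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.power import TTestIndPower

from .io import NO_AMPLIFICATION

DEFAULT_CT_CUTOFF = 35.0  # cycles; later McrBC Cts are treated as low-template
DEFAULT_SD_CUTOFF = 1.5  # cycles; larger replicate scatter likewise

FLAG_NEGATIVE_CLAMPED = "negative_clamped"
FLAG_LOW_TEMPLATE = "low_template"
FLAG_NOT_EVALUATED = "not_evaluated"


@dataclass(frozen=True)
class EfficiencyFit:
    """Per-cycle amplification factor fitted from a dilution standard curve."""

    efficiency: float
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        if self.efficiency <= 1:
            raise ValueError("efficiency must exceed 1")
        if self.efficiency > 2.05:
            warnings.warn(
                f"fitted efficiency {self.efficiency:.3f} exceeds the theoretical "
                "maximum of 2; check the dilution series"
            )


def calibrate_efficiency(dilution_series) -> EfficiencyFit:
    """Least-squares fit of Ct against log10(relative amount).

    ``dilution_series`` is an iterable of (relative_amount, ct) pairs with
    at least three distinct dilution levels; efficiency = 10^(-1/slope).
    """
    pairs = [(float(a), float(c)) for a, c in dilution_series]
    if any(a <= 0 for a, _ in pairs):
        raise ValueError("relative amounts must be positive")
    if len({a for a, _ in pairs}) < 3:
        raise ValueError("need at least 3 distinct dilution levels")
    x = np.log10([a for a, _ in pairs])
    y = np.array([c for _, c in pairs])
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError("non-negative slope: dilution series looks inverted")
    return EfficiencyFit(
        efficiency=10.0 ** (-1.0 / fit.slope),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
    )


@dataclass
class RawEstimate:
    percent: float | None
    raw: float | None
    flags: set = field(default_factory=set)


def percent_methylation(ct_mcrbc: float, ct_mock: float,
                        efficiency: float = 2.0) -> RawEstimate:
    """Single-measurement percent methylation from a McrBC/mock Ct pair."""
    if efficiency <= 1:
        raise ValueError(f"efficiency must exceed 1: {efficiency}")
    mcrbc_missing = ct_mcrbc is None or (isinstance(ct_mcrbc, float) and math.isnan(ct_mcrbc))
    mock_missing = ct_mock is None or (isinstance(ct_mock, float) and math.isnan(ct_mock))
    if mcrbc_missing and mock_missing:
        return RawEstimate(None, None, {FLAG_NOT_EVALUATED})
    if mcrbc_missing or mock_missing:
        return RawEstimate(None, None, {FLAG_NOT_EVALUATED})
    if ct_mcrbc == NO_AMPLIFICATION:
        # complete digestion; trustworthiness judged at aggregation
        return RawEstimate(100.0, 100.0, set())
    raw = 100.0 * (1.0 - efficiency ** (-(ct_mcrbc - ct_mock)))
    if raw < 0:
        return RawEstimate(0.0, raw, {FLAG_NEGATIVE_CLAMPED})
    return RawEstimate(raw, raw, set())


@dataclass
class MethylationEstimate:
    sample: str
    fragment: str
    percent: float | None  # None when withheld (low_template / not_evaluated)
    se: float
    flags: set
    n_digestions: int
    n_pcr_replicates: int

    def __post_init__(self) -> None:
        if self.percent is not None and not 0 <= self.percent <= 100:
            raise ValueError(f"percent outside [0, 100]: {self.percent}")


def aggregate_replicates(ct_rows: pd.DataFrame, efficiency: float = 2.0,
                         ct_cutoff: float = DEFAULT_CT_CUTOFF,
                         sd_cutoff: float = DEFAULT_SD_CUTOFF) -> MethylationEstimate:
    """Aggregate the Ct rows of one sample x fragment into one estimate.

    Each McrBC replicate is scored against its digestion's mean mock Ct;
    digestion-level means are averaged and their scatter gives the SE
    (replicate scatter when only one digestion is present).  The estimate
    is withheld (``percent=None``) when any McrBC Ct exceeds ``ct_cutoff``
    cycles or within-digestion replicate SD exceeds ``sd_cutoff`` cycles.
    """
    if ct_rows.empty:
        raise ValueError("no Ct rows to aggregate")
    samples = ct_rows["sample"].unique()
    fragments = ct_rows["fragment"].unique()
    if len(samples) > 1 or len(fragments) > 1:
        raise ValueError("aggregate_replicates expects a single sample x fragment")

    flags: set = set()
    digestion_means: list[float] = []
    replicate_percents: list[float] = []
    n_reps = 0
    for _, grp in ct_rows.groupby("digestion"):
        mock = grp.loc[grp["treatment"] == "mock", "ct"]
        mcrbc = grp.loc[grp["treatment"] == "mcrbc", "ct"]
        mock_mean = float(mock.replace(NO_AMPLIFICATION, np.nan).mean())
        finite_mcrbc = mcrbc[np.isfinite(mcrbc)]
        if (mcrbc > ct_cutoff).any():
            flags.add(FLAG_LOW_TEMPLATE)
        if len(finite_mcrbc) >= 2 and float(finite_mcrbc.std(ddof=1)) > sd_cutoff:
            flags.add(FLAG_LOW_TEMPLATE)
        percents = []
        for ct in mcrbc:
            est = percent_methylation(float(ct), mock_mean, efficiency)
            flags |= est.flags
            if est.percent is not None:
                percents.append(est.percent)
                replicate_percents.append(est.percent)
        n_reps = max(n_reps, len(mcrbc))
        if percents:
            digestion_means.append(float(np.mean(percents)))

    if not digestion_means:
        flags.add(FLAG_NOT_EVALUATED)
        return MethylationEstimate(str(samples[0]), str(fragments[0]), None, math.nan,
                                   flags, 0, n_reps)
    mean = float(np.mean(digestion_means))
    if len(digestion_means) >= 2:
        se = float(np.std(digestion_means, ddof=1) / math.sqrt(len(digestion_means)))
    elif len(replicate_percents) >= 2:
        se = float(np.std(replicate_percents, ddof=1) / math.sqrt(len(replicate_percents)))
    else:
        se = math.nan
    percent = None if FLAG_LOW_TEMPLATE in flags else min(max(mean, 0.0), 100.0)
    return MethylationEstimate(str(samples[0]), str(fragments[0]), percent, se, flags,
                               len(digestion_means), n_reps)


def estimate_table(ct_table: pd.DataFrame, efficiency: float = 2.0,
                   efficiency_by_fragment: dict[str, float] | None = None,
                   **kw) -> list[MethylationEstimate]:
    """One aggregated estimate per sample x fragment in a Ct table."""
    out = []
    for (sample, fragment), grp in ct_table.groupby(["sample", "fragment"], sort=True):
        e = (efficiency_by_fragment or {}).get(str(fragment), efficiency)
        out.append(aggregate_replicates(grp, efficiency=e, **kw))
    return out


@dataclass
class GroupComparison:
    difference: float  # mean(a) - mean(b)
    t: float
    p: float
    significant: bool
    alpha: float


def compare_groups(group_a, group_b, alpha: float = 0.05,
                   welch: bool = True) -> GroupComparison:
    """Two-sided two-sample t-test (Welch by default) on percent estimates."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: exact-equality shortcut
        p = 1.0 if math.isclose(a.mean(), b.mean()) else 0.0
        return GroupComparison(diff, 0.0 if p == 1.0 else math.inf, p, p <= alpha, alpha)
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(diff, float(t), float(p), bool(p <= alpha), alpha)


def required_sample_size(observed_sd: float, detectable_difference: float,
                         alpha: float = 0.05, power: float = 0.8) -> int:
    """Smallest per-group n for a two-sample t-test at the given power."""
    if observed_sd <= 0:
        raise ValueError("observed_sd must be positive")
    if detectable_difference <= 0:
        raise ValueError("detectable difference must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    effect = detectable_difference / observed_sd
    n = TTestIndPower().solve_power(effect_size=effect, alpha=alpha, power=power,
                                    alternative="two-sided")
    return int(math.ceil(n))
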