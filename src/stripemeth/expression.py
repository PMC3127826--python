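"""Efficiency-corrected relative transcript quantification.

ratio(a vs b) = E_target^(mean Ct_target,b - mean Ct_target,a)
              / E_ref^(mean Ct_ref,b - mean Ct_ref,a)

With both efficiencies equal to E this reduces to the familiar
E^-(ddCt).  The SE comes from first-order propagation of the replicate
Ct variances onto the log ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RelativeExpression:
    ratio: float
    se: float
    log_ratio: float
    log_se: float


def _mean_var_n(cts) -> tuple[float, float, int]:
    x = np.asarray(list(cts), dtype=float)
    if x.size == 0 or not np.isfinite(x).all():
        raise ValueError("Ct replicates must be non-empty and finite")
    var = float(x.var(ddof=1)) if x.size > 1 else 0.0
    return float(x.mean()), var, int(x.size)


def relative_expression(target_cts_a, target_cts_b, ref_cts_a, ref_cts_b,
                        e_target: float = 2.0, e_ref: float = 2.0) -> RelativeExpression:
    """Expression of sample a relative to sample b, normalized to a reference gene."""
    for label, e in (("target", e_target), ("reference", e_ref)):
        if not 1 < e <= 2:
            raise ValueError(f"{label} efficiency must be in (1, 2]: {e}")
    ta, var_ta, n_ta = _mean_var_n(target_cts_a)
    tb, var_tb, n_tb = _mean_var_n(target_cts_b)
    ra, var_ra, n_ra = _mean_var_n(ref_cts_a)
    rb, var_rb, n_rb = _mean_var_n(ref_cts_b)
    log_ratio = math.log(e_target) * (tb - ta) - math.log(e_ref) * (rb - ra)
    log_var = (math.log(e_target) ** 2 * (var_ta / n_ta + var_tb / n_tb)
               + math.log(e_ref) ** 2 * (var_ra / n_ra + var_rb / n_rb))
    ratio = math.exp(log_ratio)
    log_se = math.sqrt(log_var)
    return RelativeExpression(ratio=ratio, se=ratio * log_se,
                              log_ratio=log_ratio, log_se=log_se)


@dataclass
class RatioTest:
    t: float
    p: float
    significant: bool
    alpha: float
    mean_ratio: float


def ratio_greater_than_one_test(ratios, alpha: float = 0.05) -> RatioTest:
    """One-sided one-sample t-test of log(ratio) against 0."""
    r = np.asarray(list(ratios), dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 replicate ratios")
    if (r <= 0).any():
        raise ValueError("ratios must be positive")
    logs = np.log(r)
    if logs.std(ddof=1) == 0:
        # all ratios identical: significant only if they genuinely exceed 1
        p = 0.0 if logs.mean() > 0 else 1.0
        return RatioTest(math.inf if p == 0 else 0.0, p, p <= alpha, alpha,
                         float(np.exp(logs.mean())))
    t, p = stats.ttest_1samp(logs, 0.0, alternative="greater")
    return RatioTest(float(t), float(p), bool(p <= alpha), alpha,
                     float(np.exp(logs.mean())))


def expression_table(ct_table: pd.DataFrame, ref_gene: str,
                     sample_a: str, sample_b: str,
                     efficiencies: dict[str, float] | None = None,
                     default_efficiency: float = 2.0,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene a-vs-b expression ratios from a Ct table with a ``gene`` column.

    Expected columns: gene, sample, replicate, ct.  Returns one row per
    non-reference gene with ratio, SE and a significance star for
    ratio > 1 across replicate-wise ratios.
    """
    if "gene" not in ct_table.columns:
        raise ValueError("expression Ct table needs a 'gene' column")
    efficiencies = efficiencies or {}
    genes = [g for g in ct_table["gene"].unique() if g != ref_gene]
    ref = ct_table[ct_table["gene"] == ref_gene]
    if ref.empty:
        raise ValueError(f"reference gene {ref_gene!r} absent from table")
    ref_a = ref.loc[ref["sample"] == sample_a, "ct"].to_numpy(dtype=float)
    ref_b = ref.loc[ref["sample"] == sample_b, "ct"].to_numpy(dtype=float)
    e_ref = efficiencies.get(ref_gene, default_efficiency)
    rows = []
    for gene in genes:
        sub = ct_table[ct_table["gene"] == gene]
        a = sub.loc[sub["sample"] == sample_a, "ct"].to_numpy(dtype=float)
        b = sub.loc[sub["sample"] == sample_b, "ct"].to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError(f"gene {gene!r} missing Cts for one sample")
        e_t = efficiencies.get(gene, default_efficiency)
        res = relative_expression(a, b, ref_a, ref_b, e_t, e_ref)
        n = min(a.size, b.size, ref_a.size, ref_b.size)
        if n >= 2:
            rep_ratios = [
                relative_expression([a[i]], [b[i]], [ref_a[i]], [ref_b[i]],
                                    e_t, e_ref).ratio
                for i in range(n)
            ]
            test = ratio_greater_than_one_test(rep_ratios, alpha=alpha)
            p, star = test.p, "*" if test.significant else ""
        else:
            p, star = math.nan, ""
        rows.append({"gene": gene, "ratio": res.ratio, "se": res.se,
                     "p_greater_than_1": p, "significant": star})
    return pd.DataFrame(rows)
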