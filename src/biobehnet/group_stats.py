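"""Differential-prediction statistics for imputed molecular markers.

The imputed expression level of each unobserved molecular marker, averaged
over the subject group, is compared to the level predicted for the idealized
control by a two-sided one-sample t-test; p-values are corrected across all
tested markers with the Benjamini-Hochberg step-up procedure at a target
false discovery rate q (default 5%).

Four-level integer predictions often have zero variance across a small
group.  That degenerate case is handled explicitly rather than silently:
all values equal to the reference give t = 0, p = 1 (no evidence of a
difference); all values equal to each other but different from the
reference give a unanimity flag with p set to 0 and a warning, since the
t statistic is undefined there while the predicted shift is systematic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    pass


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def one_sample_t(values, mu0: float) -> TTestResult:
    """Two-sided one-sample t-test of ``values`` against ``mu0``.

    t = (mean - mu0) / (sd / sqrt(n)) with n-1 degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatsError("one-sample t-test needs at least 2 values")
    n = x.size
    if np.std(x, ddof=1) == 0.0:
        if np.isclose(x.mean(), mu0):
            return TTestResult(t=0.0, df=n - 1, p=1.0)
        warnings.warn(
            "zero-variance sample differs from the reference: t undefined, "
            "reporting p=0 with a degeneracy flag", RuntimeWarning, stacklevel=2)
        t = float(np.sign(x.mean() - mu0)) * float("inf")
        return TTestResult(t=t, df=n - 1, p=0.0, degenerate=True)
    res = stats.ttest_1samp(x, popmean=mu0)
    return TTestResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue))


def bh_adjust(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction.

    Returns (adjusted p-values, reject flags at level q), in the original
    order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise StatsError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise StatsError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def differential_markers(imputed: list[dict[str, int]],
                         control: dict[str, int],
                         markers: list[str],
                         q: float = 0.05) -> pd.DataFrame:
    """Per-marker group-vs-control table with BH-corrected significance.

    ``imputed`` holds one full imputed state per subject; ``control`` the
    state imputed for the idealized control.  Returns a DataFrame indexed by
    marker with mean level, control level, t, df, raw and adjusted p,
    direction (up/down/none) and significance flag at FDR q.
    """
    if len(imputed) < 2:
        raise StatsError("differential testing needs at least 2 subjects")
    rows = []
    for m in markers:
        if m not in control:
            raise StatsError(f"control state lacks marker {m!r}")
        vals = []
        for state in imputed:
            if m not in state:
                raise StatsError(f"an imputed state lacks marker {m!r}")
            vals.append(state[m])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = one_sample_t(vals, control[m])
        rows.append({
            "marker": m,
            "mean_level": float(np.mean(vals)),
            "control_level": control[m],
            "t": res.t,
            "df": res.df,
            "p": res.p,
            "degenerate": res.degenerate,
        })
    df = pd.DataFrame(rows).set_index("marker")
    p_adj, reject = bh_adjust(df["p"].to_numpy(), q=q)
    df["p_adj"] = p_adj
    df["significant"] = reject
    direction = []
    for m, row in df.iterrows():
        if not row["significant"]:
            direction.append("none")
        elif row["mean_level"] > row["control_level"]:
            direction.append("up")
        else:
            direction.append("down")
    df["direction"] = direction
    return df
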