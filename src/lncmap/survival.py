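"""Kaplan-Meier estimation, signed log-rank testing, and prognostic calls.

Sign convention (frozen): the log-rank Z compares the HIGH-expression group
to its expectation, Z = (E1 - O1) / sqrt(V), so Z > 0 means the high group
had FEWER observed events than expected, i.e. better survival.  A feature is
``favorable`` when Z > z_cut (overexpression associates with longer overall
survival) and ``unfavorable`` when Z < -z_cut.  This convention matters:
sign errors silently flip the biology.

Tied event times use the standard aggregated hypergeometric variance of the
log-rank test (no Efron-style correction; this is not a Cox model).
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from scipy import stats

CLASS_FAVORABLE = "favorable"
CLASS_UNFAVORABLE = "unfavorable"
CLASS_NONE = "none"


def km_curve(times: Iterable[float], events: Iterable[int]) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step function as a DataFrame with columns ``time``,
    ``n_at_risk``, ``n_events`` and ``survival``; the curve starts at
    S(0) = 1 and is non-increasing.
    """
    t = np.asarray(list(times), dtype=float)
    e = np.asarray(list(events), dtype=int)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    rows = [(0.0, len(t), 0, 1.0)]
    surv = 1.0
    for ut in np.unique(t[e == 1]):
        at_risk = int((t >= ut).sum())
        d = int(((t == ut) & (e == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append((float(ut), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank(
    times: Iterable[float], events: Iterable[int], group: Iterable
) -> tuple[float, float]:
    """Two-group log-rank test with a signed Z.

    ``group`` is truthy for the high group.  Z = (E1 - O1)/sqrt(V) where O1
    and E1 are the high group's observed and expected event counts and V the
    hypergeometric variance summed over event times.  If either group lacks
    an observed event the test is uninformative: returns (0, 1) with a
    warning.
    """
    t = np.asarray(list(times), dtype=float)
    e = np.asarray(list(events), dtype=int)
    g = np.asarray([bool(x) for x in group])
    if not (t.shape == e.shape == g.shape):
        raise ValueError("times, events, group must have equal length")
    if (e[g] == 1).sum() == 0 or (e[~g] == 1).sum() == 0:
        warnings.warn("a group has no observed events; log-rank undefined",
                      stacklevel=2)
        return 0.0, 1.0
    o1 = 0.0
    e1 = 0.0
    v = 0.0
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        n = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        d = int(((t == ut) & (e == 1)).sum())
        d1 = int(((t == ut) & (e == 1) & g).sum())
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v <= 0:
        warnings.warn("log-rank variance is zero", stacklevel=2)
        return 0.0, 1.0
    z = (e1 - o1) / np.sqrt(v)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(z), p


def classify_prognostic(
    expr: pd.DataFrame,
    survival_table: pd.DataFrame,
    z_cut: float = 1.96,
    max_tie_fraction: float = 0.5,
) -> pd.DataFrame:
    """Median-split prognostic classification per feature.

    For each feature, samples strictly above the median form the high group
    and the rest the low group; the signed log-rank Z then yields
    ``favorable`` (Z > z_cut), ``unfavorable`` (Z < -z_cut) or ``none``.
    Features with more than ``max_tie_fraction`` of values tied at the
    median cannot be split with acceptable balance and are called ``none``
    with a warning.
    """
    surv = survival_table.set_index("sample_id")
    common = [s for s in expr.columns if s in surv.index]
    if len(common) < 8:
        raise ValueError("need at least 8 samples shared by expression and survival")
    surv = surv.loc[common]
    t = surv["time"].to_numpy(dtype=float)
    e = surv["event"].to_numpy(dtype=int)
    rows = []
    for feature, values in expr[common].iterrows():
        x = values.to_numpy(dtype=float)
        med = float(np.median(x))
        tie_frac = float((x == med).mean())
        if tie_frac > max_tie_fraction:
            warnings.warn(
                f"{feature}: {tie_frac:.0%} of samples tied at the median; "
                "split infeasible",
                stacklevel=2,
            )
            rows.append((feature, 0.0, 1.0, CLASS_NONE))
            continue
        high = x > med
        if high.sum() == 0 or (~high).sum() == 0:
            rows.append((feature, 0.0, 1.0, CLASS_NONE))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z, p = logrank(t, e, high)
        if z > z_cut:
            cls = CLASS_FAVORABLE
        elif z < -z_cut:
            cls = CLASS_UNFAVORABLE
        else:
            cls = CLASS_NONE
        rows.append((feature, z, p, cls))
    return pd.DataFrame(rows, columns=["feature_id", "Z", "p", "class"])
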