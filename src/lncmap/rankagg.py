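"""Robust rank aggregation via order statistics, with leave-one-out averaging.

Given m ranked lists over a universe of N items, each item gets a normalized
rank vector r (rank/N per list; 1 for lists that omit the item).  For the
sorted vector r_(1) <= ... <= r_(m), the score at position k is the
probability that the k-th order statistic of m iid Uniform(0,1) variables is
at most r_(k):

    beta_score(r_(k), k, m) = sum_{j=k..m} C(m, j) r_(k)^j (1 - r_(k))^(m-j)

i.e. a binomial upper tail.  The rho score is the minimum over k, and the
item's p-value is the Bonferroni bound min(rho * m, 1).  Stability is
assessed by re-running the aggregation m times leaving one list out and
averaging the m p-values (arithmetic mean by default), which is then BH
corrected over the universe.

This is a fresh implementation of the order-statistic aggregation scheme;
only the binomial tail itself comes from scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .multitest import bh_adjust


@dataclass
class RankedList:
    """An ordered list of item ids, best first, drawn from a universe of size N."""

    items: list[str]
    universe_size: int
    label: str = ""

    def __post_init__(self) -> None:
        self.items = [str(i) for i in self.items]
        if len(set(self.items)) != len(self.items):
            raise ValueError(f"ranked list {self.label!r} contains duplicates")
        if len(self.items) > self.universe_size:
            raise ValueError(
                f"ranked list {self.label!r} longer than its universe "
                f"({len(self.items)} > {self.universe_size})"
            )


def _as_lists(lists: Sequence, universe: Sequence[str]) -> list[RankedList]:
    out = []
    n = len(universe)
    for i, lst in enumerate(lists):
        if isinstance(lst, RankedList):
            out.append(lst)
        else:
            out.append(RankedList(list(lst), universe_size=n, label=f"list{i}"))
    return out


def normalized_ranks(lists: Sequence, universe: Sequence[str]) -> pd.DataFrame:
    """Item x list matrix of normalized ranks; missing entries are 1.

    ``r[item, j] = rank_j(item) / N`` where N is the universe size of list j
    (ranks are 1-based), and 1 for lists not containing the item.
    """
    universe = [str(u) for u in universe]
    uset = set(universe)
    rls = _as_lists(lists, universe)
    r = np.ones((len(universe), len(rls)))
    pos = {item: i for i, item in enumerate(universe)}
    for j, rl in enumerate(rls):
        outside = set(rl.items) - uset
        if outside:
            raise ValueError(
                f"list {rl.label!r} contains items outside the universe: "
                f"{sorted(outside)[:5]}"
            )
        for rank, item in enumerate(rl.items, start=1):
            r[pos[item], j] = rank / rl.universe_size
    return pd.DataFrame(r, index=pd.Index(universe, name="item"),
                        columns=[rl.label or f"list{j}" for j, rl in enumerate(rls)])


def beta_score(r_k: float, k: int, m: int) -> float:
    """P(k-th order statistic of m iid Uniform(0,1) <= r_k)."""
    if not 1 <= k <= m:
        raise ValueError(f"k must be in 1..m, got k={k}, m={m}")
    if not 0.0 <= r_k <= 1.0:
        raise ValueError(f"normalized rank must be in [0, 1], got {r_k}")
    return float(stats.binom.sf(k - 1, m, r_k))


def rho_and_p(r_vector: Iterable[float]) -> tuple[float, float]:
    """(rho, p) for one item's normalized rank vector.

    rho = min_k beta_score(r_(k), k, m); p = min(rho * m, 1) is the
    Bonferroni bound over the m positions.  For m = 1 the p-value equals the
    normalized rank exactly.
    """
    r = np.sort(np.asarray(list(r_vector), dtype=float))
    m = r.size
    if m == 0:
        raise ValueError("empty rank vector")
    ks = np.arange(1, m + 1)
    scores = stats.binom.sf(ks - 1, m, r)
    rho = float(scores.min())
    return rho, float(min(rho * m, 1.0))


def _aggregate_matrix(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized rho/p over an item x list matrix of normalized ranks."""
    r_sorted = np.sort(r, axis=1)
    m = r.shape[1]
    scores = np.empty_like(r_sorted)
    for k in range(1, m + 1):
        scores[:, k - 1] = stats.binom.sf(k - 1, m, r_sorted[:, k - 1])
    rho = scores.min(axis=1)
    return rho, np.minimum(rho * m, 1.0)


def aggregate(lists: Sequence, universe: Sequence[str]) -> pd.DataFrame:
    """Single-pass aggregation: per-item rho and Bonferroni-bounded p."""
    r = normalized_ranks(lists, universe)
    rho, p = _aggregate_matrix(r.to_numpy())
    return pd.DataFrame({"rho": rho, "p": p}, index=r.index)


def aggregate_with_loo(
    lists: Sequence,
    universe: Sequence[str],
    alpha: float = 0.05,
    geometric: bool = False,
) -> pd.DataFrame:
    """Full aggregation plus m leave-one-out reruns and BH over the universe.

    Returns per item: ``rho``, ``p`` (full aggregation), ``loo_mean_p``
    (mean of the m leave-one-out p-values; arithmetic by default, geometric
    optionally), ``adj_p`` (BH over the universe on loo_mean_p) and
    ``significant`` at ``adj_p < alpha``.  With a single list the
    leave-one-out stage degenerates to the list itself (warned).
    """
    r = normalized_ranks(lists, universe)
    mat = r.to_numpy()
    m = mat.shape[1]
    rho, p = _aggregate_matrix(mat)
    if m < 2:
        warnings.warn(
            "leave-one-out needs at least two lists; using the single-list p",
            stacklevel=2,
        )
        loo_mean = p.copy()
    else:
        loo_ps = np.empty((mat.shape[0], m))
        for j in range(m):
            sub = np.delete(mat, j, axis=1)
            _, loo_ps[:, j] = _aggregate_matrix(sub)
        if geometric:
            loo_mean = np.exp(np.log(loo_ps).mean(axis=1))
        else:
            loo_mean = loo_ps.mean(axis=1)
    adj = bh_adjust(loo_mean)
    out = pd.DataFrame(
        {
            "rho": rho,
            "p": p,
            "loo_mean_p": loo_mean,
            "adj_p": adj,
            "significant": adj < alpha,
        },
        index=r.index,
    )
    return out


def fisher_combine(p_values: Iterable[float]) -> tuple[float, int, float]:
    """Fisher's method for one-tailed p-values: chi2 = -2 sum ln p, df = 2k."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))
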