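"""Hypergeometric over-representation shared by the module and profile stages.

The tail is always the upper one, P(X >= k): "enriched" means more overlap
than expected under uniform draws from the universe.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .multitest import bh_adjust


def hypergeom_upper_tail(k: int, n_universe: int, n_marked: int, n_drawn: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N=n_universe, K=n_marked, n=n_drawn)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_universe, n_marked, n_drawn))


def enrich_collection(
    query: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of ``query`` against every set.

    Set members outside the universe are ignored; BH adjustment is applied
    across the sets of this collection.  Rows are sorted by (adj_p, p, name)
    so ties break deterministically.
    """
    universe_set = set(universe)
    query_set = set(query) & universe_set
    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & universe_set
        overlap = len(query_set & members)
        p = hypergeom_upper_tail(overlap, len(universe_set), len(members), len(query_set))
        rows.append((name, len(members), overlap, p))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p"])
    df["adj_p"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df.sort_values(["adj_p", "p", "set_name"], kind="mergesort").reset_index(
        drop=True
    )
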