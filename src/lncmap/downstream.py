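"""Validation analytics around the core network: partner profiling,
proliferation-activity grouping, treatment fold-change screening, TSS-peak
proximity, quartile contrasts, and small statistical utilities."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from . import io
from .enrich import enrich_collection
from .multitest import bh_adjust
from .rankagg import RankedList
from .regnet import AssociationNetwork

#: the eight broad functional categories hallmark-type signatures fall into
HALLMARK_CATEGORIES = (
    "proliferation",
    "signaling",
    "immune",
    "metabolic",
    "DNA damage",
    "development",
    "cellular component",
    "pathway",
)


@dataclass
class GeneSetCollection:
    """Named gene sets with a collection label and optional category map."""

    sets: dict[str, list[str]]
    label: str = ""
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {
            str(k): list(dict.fromkeys(map(str, v))) for k, v in self.sets.items()
        }

    def members(self) -> set[str]:
        out: set[str] = set()
        for v in self.sets.values():
            out.update(v)
        return out

    def to_gmt(self, path) -> None:
        io.write_gmt(self.sets, path, descriptions=self.categories or None)

    @classmethod
    def from_gmt(cls, path, label: str = "",
                 categories: Optional[Mapping[str, str]] = None) -> "GeneSetCollection":
        sets = io.read_gmt(path)
        return cls(sets, label=label, categories=dict(categories or {}))


def top_k_partners(
    network: AssociationNetwork,
    lncrna_id: str,
    k: int = 200,
    direction: str = "positive",
) -> list[str]:
    """The k most positively (or negatively) associated genes of one lncRNA.

    Ranks ALL fitted genes of the lncRNA by coefficient (largest b_lnc for
    ``positive``, smallest for ``negative``); fewer than k available returns
    the full list with a warning.  Coefficient ties break by gene id.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    coefs = network.coefficients(lncrna_id).dropna()
    asc = direction == "negative"
    ordered = coefs.sort_index(kind="mergesort").sort_values(
        ascending=asc, kind="mergesort"
    )
    if len(ordered) < k:
        warnings.warn(
            f"{lncrna_id}: only {len(ordered)} fitted partners available "
            f"(requested {k})",
            stacklevel=2,
        )
    return list(ordered.index[:k])


def hallmark_profile(
    lncrna_id: str,
    partner_lists: Mapping[str, Sequence[str]],
    genesets: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
    top_k: int = 5,
) -> pd.DataFrame:
    """Top enriched signatures per partner list (direction attached).

    ``partner_lists`` maps direction ("positive"/"negative") to a gene list,
    typically the top-200 partners per direction.  Enrichment is
    hypergeometric with BH across the collection's sets per direction; the
    ``top_k`` significant sets are reported with their category.
    """
    universe = list(universe)
    frames = []
    for direction, genes in partner_lists.items():
        res = enrich_collection(genes, genesets.sets, universe)
        sig = res[res["adj_p"] < alpha].head(top_k).copy()
        sig.insert(0, "direction", direction)
        sig.insert(0, "lncrna_id", lncrna_id)
        frames.append(sig)
    if not frames:
        return pd.DataFrame(
            columns=["lncrna_id", "direction", "set_name", "set_size", "overlap",
                     "p", "adj_p", "category"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["category"] = out["set_name"].map(genesets.categories).fillna("unknown")
    return out


def category_counts(
    profiles: pd.DataFrame, categories: Sequence[str] = HALLMARK_CATEGORIES
) -> pd.Series:
    """Number of distinct lncRNAs whose profile touches each category."""
    counts = {
        c: profiles.loc[profiles["category"] == c, "lncrna_id"].nunique()
        for c in categories
    }
    return pd.Series(counts, name="n_lncrnas")


def category_anova(count_table: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA of per-cohort lncRNA counts across categories.

    ``count_table`` is category x cohort; cohorts are the replicates.  A
    table with zero between- and within-category variance returns (0, 1).
    """
    groups = [row.to_numpy(dtype=float) for _, row in count_table.iterrows()]
    if len(groups) < 2:
        raise ValueError("need at least two categories")
    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def proliferation_groups(
    expression: pd.DataFrame,
    proliferation_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-sample proliferation activity scores and quartile groups.

    The score is the mean expression over the union of the configured
    proliferation gene sets (genes present in the matrix).  Samples are
    ranked by score (ties broken by sample id) and the bottom and top
    floor(n/4) samples labelled ``lower``/``upper``; the rest ``middle``.
    """
    union: set[str] = set()
    for genes in proliferation_sets.values():
        union.update(map(str, genes))
    present = [g for g in expression.index if g in union]
    if not present:
        raise ValueError("no proliferation genes present in the expression matrix")
    scores = expression.loc[present].mean(axis=0)
    order = scores.to_frame("score")
    order["sample_id"] = order.index
    order = order.sort_values(["score", "sample_id"], kind="mergesort")
    n = len(order)
    q = n // 4
    group = pd.Series("middle", index=order.index, name="group")
    group.iloc[:q] = "lower"
    if q > 0:
        group.iloc[n - q:] = "upper"
    out = pd.DataFrame({"score": scores, "group": group.reindex(scores.index)})
    out.index.name = "sample_id"
    return out


def group_differential(
    expr: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    high_label: str = "upper",
    low_label: str = "lower",
) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum of high- vs low-activity samples.

    Returns log2 median fold change (pseudocount = half the smallest positive
    value in the matrix), the two-sided rank-sum p, and the BH q-value.
    """
    high = groups.index[groups == high_label]
    low = groups.index[groups == low_label]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both groups must be non-empty")
    hi = expr[high].to_numpy(dtype=float)
    lo = expr[low].to_numpy(dtype=float)
    positive = expr.to_numpy()[expr.to_numpy() > 0]
    pseudo = 0.5 * positive.min() if positive.size else 0.5
    log2fc = np.log2(
        (np.median(hi, axis=1) + pseudo) / (np.median(lo, axis=1) + pseudo)
    )
    pvals = np.array(
        [
            stats.mannwhitneyu(hi[i], lo[i], alternative="two-sided").pvalue
            for i in range(expr.shape[0])
        ]
    )
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "q": bh_adjust(pvals)}, index=expr.index
    )
    out["significant"] = out["q"] < alpha
    return out


@dataclass
class TreatmentScreenResult:
    """Per-feature log2 fold change and the >= 2-fold up/down lists."""

    log2fc: pd.Series
    up: list[str]
    down: list[str]
    fc_threshold: float

    def ranked_lists(self, universe_size: int, label: str = "") -> dict[str, RankedList]:
        return {
            "up": RankedList(self.up, universe_size, label=f"{label}:up"),
            "down": RankedList(self.down, universe_size, label=f"{label}:down"),
        }


def treatment_screen(
    counts_treated: pd.DataFrame,
    counts_control: pd.DataFrame,
    fc_threshold: float = 2.0,
) -> TreatmentScreenResult:
    """Fold-change screen on one treated/control count-matrix pair.

    Counts are normalized by total library size (mean library as reference),
    averaged per group, and log2 fold changes taken with pseudocount 0.5.
    The up list holds features with FC >= threshold ranked by descending
    log2FC, the down list features with FC <= 1/threshold ranked ascending;
    ties break by feature id.  Swapping the two matrices negates every
    log2FC exactly.
    """
    if not counts_treated.index.equals(counts_control.index):
        raise ValueError("treated and control matrices must share the feature index")
    ref = np.concatenate(
        [counts_treated.sum(axis=0).to_numpy(), counts_control.sum(axis=0).to_numpy()]
    ).mean()

    def _group_mean(counts: pd.DataFrame) -> np.ndarray:
        lib = counts.sum(axis=0).to_numpy(dtype=float)
        norm = counts.to_numpy(dtype=float) / lib * ref
        return norm.mean(axis=1)

    mt = _group_mean(counts_treated)
    mc = _group_mean(counts_control)
    log2fc = pd.Series(
        np.log2((mt + 0.5) / (mc + 0.5)), index=counts_treated.index, name="log2fc"
    )
    cut = np.log2(fc_threshold)
    up = log2fc[log2fc >= cut]
    down = log2fc[log2fc <= -cut]
    up_order = (
        up.to_frame("v").assign(fid=up.index.astype(str))
        .sort_values(["v", "fid"], ascending=[False, True], kind="mergesort")
    )
    down_order = (
        down.to_frame("v").assign(fid=down.index.astype(str))
        .sort_values(["v", "fid"], ascending=[True, True], kind="mergesort")
    )
    return TreatmentScreenResult(
        log2fc, list(up_order.index), list(down_order.index), fc_threshold
    )


def tss_proximity(
    peaksets: Sequence[pd.DataFrame],
    tss_table: pd.DataFrame,
    window: int = 10000,
) -> pd.Series:
    """Per lncRNA: number of peak datasets with >= 1 peak within ``window``.

    Peaks are 0-based half-open [start, end); the 1-based TSS is converted to
    a 0-based point t and a dataset counts when any peak interval intersects
    the closed window [t - window, t + window].  The window is symmetric, so
    the count is strand-independent.
    """
    counts = pd.Series(0, index=tss_table["lncrna_id"].astype(str), name="n_datasets")
    tss0 = tss_table["tss_position"].to_numpy() - 1
    chroms = tss_table["chrom"].astype(str).to_numpy()
    for peaks in peaksets:
        trees: dict[str, IntervalTree] = {}
        for chrom, sub in peaks.groupby("chrom"):
            trees[str(chrom)] = IntervalTree.from_tuples(
                zip(sub["start"].astype(int), sub["end"].astype(int))
            )
        for i, lnc in enumerate(counts.index):
            tree = trees.get(chroms[i])
            if tree is None:
                continue
            # closed window [t-w, t+w] against half-open peaks: query the
            # half-open range [t-w, t+w+1)
            if tree.overlap(int(tss0[i]) - window, int(tss0[i]) + window + 1):
                counts.iloc[i] += 1
    return counts


def compare_proximity(
    counts: pd.Series, candidate_ids: Iterable[str]
) -> tuple[float, float]:
    """Two-sided rank-sum: candidate dataset counts vs background counts."""
    cand = set(map(str, candidate_ids))
    in_cand = counts.index.astype(str).isin(cand)
    if in_cand.sum() == 0 or (~in_cand).sum() == 0:
        raise ValueError("need non-empty candidate and background sets")
    res = stats.mannwhitneyu(
        counts[in_cand], counts[~in_cand], alternative="two-sided"
    )
    return float(res.statistic), float(res.pvalue)


def quartile_fold_change(
    expr: pd.DataFrame,
    anchor_feature: str,
    target_genes: Sequence[str],
) -> pd.Series:
    """Per-target log2 fold change, highest- vs lowest-quartile anchor samples.

    Samples are split by the anchor feature's expression (bottom/top
    floor(n/4), ties by sample id); each target gene's log2FC compares the
    median across the high-anchor group to the low-anchor group with a
    pseudocount of half the smallest positive matrix value.
    """
    if anchor_feature not in expr.index:
        raise KeyError(f"anchor feature {anchor_feature!r} not in matrix")
    anchor = expr.loc[anchor_feature]
    order = anchor.to_frame("v")
    order["sample_id"] = order.index
    order = order.sort_values(["v", "sample_id"], kind="mergesort")
    q = len(order) // 4
    if q == 0:
        raise ValueError("need at least 4 samples for quartile groups")
    low = order.index[:q]
    high = order.index[-q:]
    targets = [g for g in target_genes if g in expr.index]
    positive = expr.to_numpy()[expr.to_numpy() > 0]
    pseudo = 0.5 * positive.min() if positive.size else 0.5
    hi = expr.loc[targets, high].median(axis=1).to_numpy()
    lo = expr.loc[targets, low].median(axis=1).to_numpy()
    return pd.Series(
        np.log2((hi + pseudo) / (lo + pseudo)), index=pd.Index(targets), name="log2fc"
    )


def tukey_fences(values: Iterable[float], k: float = 1.5) -> np.ndarray:
    """Outlier flags outside [Q1 - k*IQR, Q3 + k*IQR] (linear-interp quartiles)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - k * iqr) | (v > q3 + k * iqr)
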