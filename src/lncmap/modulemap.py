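"""Co-essential module filtering, re-annotation, and lncRNA assignment.

Modules arrive with precomputed density scores and member gene lists.  The
pipeline (i) rejects syntenic modules (all members on one chromosome) and
those with density below 0.5; (ii) re-annotates each survivor with its top
five significantly enriched hallmark-type and pathway-type gene sets and
marks proliferation-linked modules; (iii) assigns an lncRNA to a module when
BOTH a hypergeometric enrichment of the lncRNA's significant partners among
the module members AND an empirical randomization test on the mean
regression coefficient pass BH-adjusted p < 0.05, with the regulation
direction taken from the sign of the average coefficient.

The randomization statistic is |mean b_lnc over module members| using the
coefficients of ALL fitted members (restricting to significant pairs would
inject selection bias into the null); null draws are same-size gene sets
sampled uniformly without replacement from the fitted universe, and the
empirical p uses the add-one (Davison-Hinkley) formula so it is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .enrich import enrich_collection, hypergeom_upper_tail
from .multitest import bh_adjust
from .regnet import AssociationNetwork

#: gene sets whose enrichment marks a module as proliferation/growth-linked
PROLIFERATION_SETS = (
    "HALLMARK_MYC_TARGETS_V1",
    "HALLMARK_MYC_TARGETS_V2",
    "HALLMARK_E2F_TARGETS",
    "HALLMARK_G2M_CHECKPOINT",
    "HALLMARK_MITOTIC_SPINDLE",
    "KEGG_CELL_CYCLE",
)


@dataclass
class CoessentialModule:
    """A co-essential module: members, a given density score in [0, 1]."""

    module_id: str
    members: list[str]
    density: float

    def __post_init__(self) -> None:
        self.members = [str(m) for m in self.members]
        if len(self.members) < 2:
            raise ValueError(f"module {self.module_id} needs >= 2 members")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"module {self.module_id} density outside [0, 1]")

    def chromosomes(self, gene_chrom: Mapping[str, str]) -> set[str]:
        return {gene_chrom[m] for m in self.members if m in gene_chrom}


class ModuleSet:
    """An ordered collection of modules with id lookup."""

    def __init__(self, modules: Sequence[CoessentialModule]):
        self.modules = list(modules)
        self._by_id = {m.module_id: m for m in self.modules}
        if len(self._by_id) != len(self.modules):
            raise ValueError("duplicate module ids")

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, module_id: str) -> CoessentialModule:
        return self._by_id[module_id]

    def __contains__(self, module_id: str) -> bool:
        return module_id in self._by_id

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "module_id": [m.module_id for m in self.modules],
                "density": [m.density for m in self.modules],
                "members": [",".join(m.members) for m in self.modules],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ModuleSet":
        df = pd.read_csv(path, sep="\t", dtype={"module_id": str, "members": str})
        return cls(
            [
                CoessentialModule(r.module_id, r.members.split(","), float(r.density))
                for r in df.itertuples()
            ]
        )


def filter_modules(
    modules: Iterable[CoessentialModule],
    gene_chrom: Mapping[str, str],
    min_density: float = 0.5,
) -> ModuleSet:
    """Drop syntenic modules and those with density < min_density (inclusive keep)."""
    kept = []
    for mod in modules:
        if mod.density < min_density:
            continue
        if len(mod.chromosomes(gene_chrom)) <= 1:
            continue
        kept.append(mod)
    return ModuleSet(kept)


@dataclass
class ModuleAnnotation:
    """Top enriched set names per collection and the proliferation flag."""

    module_id: str
    top_sets: dict[str, pd.DataFrame] = field(default_factory=dict)
    proliferation_linked: bool = False

    def significant_names(self) -> set[str]:
        names: set[str] = set()
        for df in self.top_sets.values():
            names.update(df["set_name"])
        return names


def annotate_module(
    module: CoessentialModule,
    collections: Sequence,
    universe: Iterable[str],
    alpha: float = 0.05,
    top_k: int = 5,
    proliferation_sets: Sequence[str] = PROLIFERATION_SETS,
) -> ModuleAnnotation:
    """Hypergeometric re-annotation of one module against set collections.

    For each collection (e.g. hallmark-like and pathway-like), members are
    tested for over-representation in every set, BH is applied within the
    collection, and the top ``top_k`` significant sets (adjusted p < alpha)
    are reported.  The module is proliferation-linked iff any significant
    annotation is one of ``proliferation_sets``.
    """
    ann = ModuleAnnotation(module.module_id)
    prolif = set(proliferation_sets)
    for coll in collections:
        label = getattr(coll, "label", None) or f"collection{len(ann.top_sets)}"
        sets = coll.sets if hasattr(coll, "sets") else dict(coll)
        res = enrich_collection(module.members, sets, universe)
        sig = res[res["adj_p"] < alpha]
        ann.top_sets[label] = sig.head(top_k).reset_index(drop=True)
        if bool(set(sig["set_name"]) & prolif):
            ann.proliferation_linked = True
    return ann


def annotate_modules(
    modules: Iterable[CoessentialModule],
    collections: Sequence,
    universe: Iterable[str],
    alpha: float = 0.05,
    top_k: int = 5,
    proliferation_sets: Sequence[str] = PROLIFERATION_SETS,
) -> dict[str, ModuleAnnotation]:
    universe = list(universe)
    return {
        m.module_id: annotate_module(
            m, collections, universe, alpha=alpha, top_k=top_k,
            proliferation_sets=proliferation_sets,
        )
        for m in modules
    }


def _empirical_p(null_stats: np.ndarray, observed: float) -> float:
    """Add-one empirical p-value: (1 + #{null >= obs}) / (n + 1)."""
    return float((1 + int((null_stats >= observed).sum())) / (null_stats.size + 1))


def randomization_test(
    lncrna_id: str,
    module: CoessentialModule,
    network: AssociationNetwork,
    n_draws: int = 1000,
    seed: Optional[int] = None,
    statistic: str = "abs_mean",
) -> tuple[float, float]:
    """Empirical test of lncRNA-module association strength.

    The observed statistic is |mean of b_lnc over the module members fitted
    for this lncRNA| (or the signed mean with ``statistic="mean"``); the null
    resamples same-size gene sets uniformly without replacement from the
    lncRNA's fitted-gene universe.  Returns ``(rand_p, avg_coef)`` where
    ``avg_coef`` is the signed mean.  Members not fitted for the lncRNA are
    excluded; fewer than 2 usable members raises ValueError (callers skip
    such pairs and record them).
    """
    coefs = network.coefficients(lncrna_id).dropna()
    member_mask = coefs.index.isin(module.members)
    if int(member_mask.sum()) < 2:
        raise ValueError(
            f"module {module.module_id} has < 2 members fitted for {lncrna_id}"
        )
    values = coefs.to_numpy()
    rng = np.random.default_rng(seed)
    s = int(member_mask.sum())
    idx = _distinct_draws(rng, n_draws, s, values.size)
    null_means = values[idx].mean(axis=1)
    avg_coef = float(values[member_mask].mean())
    if statistic == "abs_mean":
        obs, null = abs(avg_coef), np.abs(null_means)
    elif statistic == "mean":
        obs, null = avg_coef, null_means
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return _empirical_p(null, obs), avg_coef


def _distinct_draws(
    rng: np.random.Generator, n_draws: int, size: int, universe: int
) -> np.ndarray:
    """(n_draws x size) index matrix; each row distinct indices, uniform.

    Rejection-sampled integer rows conditioned on distinctness are uniform
    without-replacement samples; with size << universe only a few rows need
    redrawing.
    """
    if size > universe:
        raise ValueError("sample size exceeds universe")
    idx = rng.integers(0, universe, size=(n_draws, size))
    while True:
        srt = np.sort(idx, axis=1)
        bad = (srt[:, 1:] == srt[:, :-1]).any(axis=1) if size > 1 else np.zeros(
            n_draws, bool
        )
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, universe, size=(int(bad.sum()), size))


@dataclass
class AssignmentResult:
    """All tested candidate pairs, the retained edges, and skipped pairs."""

    candidates: pd.DataFrame  # every tested (lncrna, module) pair
    assignments: pd.DataFrame  # pairs passing both BH-adjusted tests
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    def edges(self) -> list[tuple[str, str, int]]:
        return list(
            zip(
                self.assignments["lncrna_id"],
                self.assignments["module_id"],
                self.assignments["direction"],
            )
        )


def assign_lncrnas(
    network: AssociationNetwork,
    modules: ModuleSet,
    annotations: Mapping[str, ModuleAnnotation],
    alpha: float = 0.05,
    n_draws: int = 1000,
    seed: Optional[int] = None,
    statistic: str = "abs_mean",
) -> AssignmentResult:
    """Assign lncRNAs to proliferation-linked modules via the dual test.

    Candidates are all (lncRNA, module) pairs where the lncRNA has at least
    one significant network partner and the module is proliferation-linked.
    Both the hypergeometric enrichment p and the randomization p are BH
    corrected over all candidate pairs (separate families per test); an edge
    is kept when both adjusted values fall below ``alpha``.  Direction is the
    sign of the average coefficient over module members.
    """
    prolif_modules = [
        m for m in modules if annotations[m.module_id].proliferation_linked
    ]
    coef = network.coefficient_matrix()
    sig_tbl = network.significant
    sig_partners = {
        lnc: set(sub["gene_id"]) for lnc, sub in sig_tbl.groupby("lncrna_id")
    }
    candidates = sorted(sig_partners)
    rng = np.random.default_rng(seed)
    skipped: list[tuple[str, str, str]] = []
    rows = []
    gene_index = coef.columns

    for lnc in candidates:
        values_all = coef.loc[lnc].to_numpy()
        fitted_mask = ~np.isnan(values_all)
        values = values_all[fitted_mask]
        fitted_genes = gene_index[fitted_mask]
        fitted_set = set(fitted_genes)
        gene_pos = {g: i for i, g in enumerate(fitted_genes)}
        partners = sig_partners[lnc] & fitted_set
        sizes = {}
        for mod in prolif_modules:
            member_genes = [m for m in mod.members if m in fitted_set]
            if len(member_genes) < 2:
                skipped.append((lnc, mod.module_id, "fewer than 2 fitted members"))
                continue
            sizes.setdefault(len(member_genes), []).append((mod, member_genes))
        if not sizes:
            continue
        max_size = max(sizes)
        idx = _distinct_draws(rng, n_draws, max_size, values.size)
        gathered = values[idx]
        csum = np.cumsum(gathered, axis=1)
        for s, mods in sizes.items():
            null_means = csum[:, s - 1] / s
            null_abs = np.abs(null_means)
            for mod, member_genes in mods:
                member_vals = values[[gene_pos[g] for g in member_genes]]
                avg_coef = float(member_vals.mean())
                if statistic == "abs_mean":
                    rand_p = _empirical_p(null_abs, abs(avg_coef))
                else:
                    rand_p = _empirical_p(null_means, avg_coef)
                overlap = len(partners & set(member_genes))
                enrich_p = hypergeom_upper_tail(
                    overlap, len(fitted_set), len(member_genes), len(partners)
                )
                rows.append(
                    (
                        lnc, mod.module_id, len(member_genes), overlap,
                        enrich_p, rand_p, avg_coef,
                    )
                )

    cand = pd.DataFrame(
        rows,
        columns=[
            "lncrna_id", "module_id", "n_members_fitted", "overlap",
            "enrich_p", "rand_p", "avg_coef",
        ],
    )
    if len(cand):
        cand["adj_enrich_p"] = bh_adjust(cand["enrich_p"].to_numpy())
        cand["adj_rand_p"] = bh_adjust(cand["rand_p"].to_numpy())
        cand["direction"] = np.sign(cand["avg_coef"]).astype(int)
        keep = (cand["adj_enrich_p"] < alpha) & (cand["adj_rand_p"] < alpha)
        assignments = cand[keep].reset_index(drop=True)
    else:
        for col in ("adj_enrich_p", "adj_rand_p", "direction"):
            cand[col] = []
        assignments = cand.copy()
    return AssignmentResult(cand, assignments, skipped)
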