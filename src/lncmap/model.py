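"""End-to-end model object: lncRNA -> co-essential-module mapping.

``ModuleMapper`` bundles the pipeline stages behind a model/results pair in
the style of statsmodels: the model holds the data and tuning parameters,
``fit()`` runs preprocessing, the per-pair regressions, module filtering and
annotation, the dual-test assignment, and the per-direction rank-aggregation
meta-analysis, returning a :class:`ModuleMapperResults` that carries every
intermediate table plus ``summary()`` and a volcano plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import modulemap, rankagg, regnet
from .downstream import GeneSetCollection
from .modulemap import AssignmentResult, ModuleAnnotation, ModuleSet
from .preprocess import PreparedCohort, prepare_cohort
from .regnet import AssociationNetwork
from .synthdata import OmicsCohort


class ModuleMapper:
    """Maps lncRNAs onto proliferation-linked co-essential modules.

    Parameters
    ----------
    cohort : OmicsCohort
        Aligned lncRNA/mRNA/methylation/copy-number matrices.
    modules : ModuleSet
        Co-essential modules with given density scores.
    genesets : sequence of GeneSetCollection
        Collections used to re-annotate modules (e.g. hallmark-like and
        pathway-like).
    essential_genes : iterable of str
        Pan-cancer essential genes for the enrichment classification.
    network_alpha : float
        BH cutoff on the per-pair regression p (default 1e-3).
    assign_alpha : float
        BH cutoff for both module-assignment tests (default 0.05).
    essential_alpha : float
        BH cutoff for essential-gene enrichment classes (default 1e-10).
    agg_alpha : float
        BH cutoff on the leave-one-out aggregation p (default 0.05).
    """

    def __init__(
        self,
        cohort: OmicsCohort,
        modules: ModuleSet,
        genesets: Sequence[GeneSetCollection],
        essential_genes,
        *,
        network_alpha: float = 1e-3,
        assign_alpha: float = 0.05,
        essential_alpha: float = 1e-10,
        agg_alpha: float = 0.05,
        min_density: float = 0.5,
        exclude_cis: bool = False,
    ):
        self.cohort = cohort
        self.modules = modules
        self.genesets = list(genesets)
        self.essential_genes = list(essential_genes)
        self.network_alpha = network_alpha
        self.assign_alpha = assign_alpha
        self.essential_alpha = essential_alpha
        self.agg_alpha = agg_alpha
        self.min_density = min_density
        self.exclude_cis = exclude_cis

    @classmethod
    def from_directory(cls, path, **kwargs) -> "ModuleMapper":
        """Build the model from a directory written by ``synthdata.write_all``."""
        from pathlib import Path

        import pandas as pd

        from .downstream import GeneSetCollection
        from .io import read_gmt

        path = Path(path)
        cohort = OmicsCohort.read(path)
        modules = ModuleSet.from_tsv(path / "modules.tsv")
        hallmark = GeneSetCollection(read_gmt(path / "hallmark.gmt"), label="hallmark")
        kegg = GeneSetCollection(read_gmt(path / "kegg.gmt"), label="kegg")
        essential = (
            pd.read_csv(path / "essential_genes.txt", header=None)[0].astype(str).tolist()
        )
        return cls(cohort, modules, [hallmark, kegg], essential, **kwargs)

    def fit(
        self, n_draws: int = 1000, seed: Optional[int] = None
    ) -> "ModuleMapperResults":
        """Run the full pipeline; ``seed`` drives the randomization test."""
        prepared = prepare_cohort(self.cohort)
        network = regnet.build_network(
            prepared, alpha=self.network_alpha, exclude_cis=self.exclude_cis
        )
        essential_classes = regnet.classify_essential(
            network, self.essential_genes, alpha=self.essential_alpha
        )
        gene_chrom = dict(
            zip(self.cohort.gene_annot["gene_id"], self.cohort.gene_annot["chrom"])
        )
        kept = modulemap.filter_modules(
            self.modules, gene_chrom, min_density=self.min_density
        )
        annotations = modulemap.annotate_modules(
            kept, self.genesets, universe=list(network.gene_ids) or
            list(prepared.mrna_z.index)
        )
        assignment = modulemap.assign_lncrnas(
            network, kept, annotations, alpha=self.assign_alpha,
            n_draws=n_draws, seed=seed,
        )
        pos_lists, neg_lists, universe = _module_rankings(
            assignment.assignments, universe=network.lncrna_ids
        )
        agg_kwargs = dict(alpha=self.agg_alpha)
        positive_agg = (
            rankagg.aggregate_with_loo(pos_lists, universe, **agg_kwargs)
            if pos_lists else _empty_agg()
        )
        negative_agg = (
            rankagg.aggregate_with_loo(neg_lists, universe, **agg_kwargs)
            if neg_lists else _empty_agg()
        )
        return ModuleMapperResults(
            model=self,
            prepared=prepared,
            network=network,
            essential_classes=essential_classes,
            modules_kept=kept,
            annotations=annotations,
            assignment=assignment,
            positive_agg=positive_agg,
            negative_agg=negative_agg,
        )


def _module_rankings(
    assignments: pd.DataFrame,
    universe: Optional[Sequence[str]] = None,
) -> tuple[list[rankagg.RankedList], list[rankagg.RankedList], list[str]]:
    """Per-module ranked lncRNA lists by association strength, per direction.

    The normalized-rank universe is the full set of network lncRNAs (not
    just the assigned ones), mirroring a meta-analysis over the whole
    candidate lncRNA space.
    """
    if universe is None:
        universe = sorted(assignments["lncrna_id"].unique()) if len(assignments) else []
    universe = sorted(map(str, universe))
    pos_lists: list[rankagg.RankedList] = []
    neg_lists: list[rankagg.RankedList] = []
    n = len(universe)
    for module_id, sub in assignments.groupby("module_id", sort=True):
        pos = sub[sub["direction"] > 0].sort_values(
            ["avg_coef", "lncrna_id"], ascending=[False, True], kind="mergesort"
        )
        neg = sub[sub["direction"] < 0].sort_values(
            ["avg_coef", "lncrna_id"], ascending=[True, True], kind="mergesort"
        )
        if len(pos):
            pos_lists.append(
                rankagg.RankedList(list(pos["lncrna_id"]), n, label=f"{module_id}:+")
            )
        if len(neg):
            neg_lists.append(
                rankagg.RankedList(list(neg["lncrna_id"]), n, label=f"{module_id}:-")
            )
    return pos_lists, neg_lists, universe


def _empty_agg() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["rho", "p", "loo_mean_p", "adj_p", "significant"]
    )


@dataclass
class ModuleMapperResults:
    """Everything the fitted pipeline produced."""

    model: ModuleMapper
    prepared: PreparedCohort
    network: AssociationNetwork
    essential_classes: pd.DataFrame
    modules_kept: ModuleSet
    annotations: Mapping[str, ModuleAnnotation]
    assignment: AssignmentResult
    positive_agg: pd.DataFrame
    negative_agg: pd.DataFrame

    @property
    def inducers(self) -> list[str]:
        """lncRNAs consistently positively associated across modules."""
        agg = self.positive_agg
        return sorted(agg.index[agg["significant"]]) if len(agg) else []

    @property
    def suppressors(self) -> list[str]:
        """lncRNAs consistently negatively associated across modules."""
        agg = self.negative_agg
        return sorted(agg.index[agg["significant"]]) if len(agg) else []

    @property
    def final_modules(self) -> list[str]:
        """Proliferation-linked modules with at least one assigned lncRNA."""
        if not len(self.assignment.assignments):
            return []
        return sorted(self.assignment.assignments["module_id"].unique())

    def association_strength(self) -> pd.Series:
        """Mean signed module-association coefficient per assigned lncRNA."""
        a = self.assignment.assignments
        if not len(a):
            return pd.Series(dtype=float, name="avg_coef")
        return a.groupby("lncrna_id")["avg_coef"].mean()

    def summary(self) -> str:
        n_prolif = sum(
            1 for ann in self.annotations.values() if ann.proliferation_linked
        )
        counts = self.essential_classes["essential_class"].value_counts()
        lines = [
            "lncRNA / co-essential module mapping",
            "=" * 44,
            f"samples:                      {len(self.prepared.samples)}",
            f"lncRNAs fitted:               {len(self.network.lncrna_ids)}",
            f"genes fitted:                 {len(self.network.gene_ids)}",
            f"pairs fitted:                 {len(self.network)}",
            f"significant pairs (BH<{self.model.network_alpha:g}): "
            f"{int(self.network.table['significant'].sum())}",
            f"EG-linked lncRNAs:            "
            f"{int((self.essential_classes['essential_class'] != 'neither').sum())}"
            f"  (+{int(counts.get('positive-enriched', 0))} / "
            f"-{int(counts.get('negative-enriched', 0))})",
            f"modules kept after filtering: {len(self.modules_kept)}",
            f"proliferation-linked modules: {n_prolif}",
            f"modules in final network:     {len(self.final_modules)}",
            f"lncRNA-module edges:          {len(self.assignment.assignments)}",
            f"consistent inducers:          {len(self.inducers)}",
            f"consistent suppressors:       {len(self.suppressors)}",
        ]
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        """Association strength vs aggregation significance per lncRNA."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        strength = self.association_strength()
        for agg, color, label in (
            (self.positive_agg, "tab:red", "positive"),
            (self.negative_agg, "tab:blue", "negative"),
        ):
            if not len(agg):
                continue
            common = strength.index.intersection(agg.index)
            x = strength.loc[common]
            y = -np.log10(np.clip(agg.loc[common, "loo_mean_p"], 1e-300, None))
            sig = agg.loc[common, "significant"]
            ax.scatter(x[~sig], y[~sig], s=8, c="0.7")
            ax.scatter(x[sig], y[sig], s=10, c=color, label=f"{label} (consistent)")
        ax.axhline(-np.log10(self.model.agg_alpha), ls="--", c="0.4", lw=0.8)
        ax.set_xlabel("mean module association coefficient")
        ax.set_ylabel("-log10 aggregation p (leave-one-out mean)")
        ax.legend(frameon=False, fontsize=8)
        return ax
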