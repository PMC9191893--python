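"""Synthetic multi-omics cohorts with planted regulatory structure.

Every input the pipeline consumes can be generated here with known ground
truth, so each stage is testable end-to-end without external data:

* mRNA expression is built additively from promoter methylation (negative
  effect, on the beta-value scale), gene copy number, planted driver-lncRNA
  terms, and Gaussian noise — the exact generative model the per-pair
  regression assumes;
* a fraction of genes are confounder-only negatives whose copy-number track
  is the genomic locus of a paired lncRNA, so naive co-expression is fooled
  while the adjusted model is not;
* three methylation probes per gene, only one anti-correlated with
  expression, exercise representative-probe selection;
* co-essential modules carry given density scores and include syntenic and
  low-density decoys the filter must reject;
* treatment/control count matrices are negative binomial with planted
  consistent fold-change shifts; survival times are exponential with
  expression-linked hazard; binding peaks are planted near a subset of
  lncRNA transcription start sites.

Determinism: one master seed; each generator derives an independent child
stream from a fixed offset, so stages can regenerate independently and a
fixed config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import SynthConfig
from .downstream import HALLMARK_CATEGORIES, GeneSetCollection
from .modulemap import CoessentialModule, ModuleSet

# fixed child-stream offsets
_STREAM_COHORT = 0
_STREAM_MODULES = 1
_STREAM_GENESETS = 2
_STREAM_TREATMENT = 3
_STREAM_SURVIVAL = 4
_STREAM_PEAKS = 5

_N_CHROMS = 22
_CHROM_LENGTH = 100_000_000


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.seed])


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _zrow(values: np.ndarray) -> np.ndarray:
    """Row-wise z-score with the sample (n-1) SD, matching the pipeline."""
    mean = values.mean(axis=-1, keepdims=True)
    sd = values.std(axis=-1, ddof=1, keepdims=True)
    return (values - mean) / sd


@dataclass
class OmicsCohort:
    """Aligned sample x feature matrices plus feature annotations."""

    lncrna_expr: pd.DataFrame  # lncRNA x sample
    mrna_expr: pd.DataFrame  # gene x sample
    methylation: pd.DataFrame  # probe x sample, beta values in [0, 1]
    probe_map: pd.DataFrame  # probe_id, gene_id
    copy_number: pd.DataFrame  # gene x sample, log-ratio-like
    gene_annot: pd.DataFrame  # gene_id, chrom
    lnc_annot: pd.DataFrame  # lncrna_id, chrom, strand, tss_position (1-based)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_matrix(self.lncrna_expr, outdir / "lncrna_expr.tsv", "lncrna_id")
        io.write_matrix(self.mrna_expr, outdir / "mrna_expr.tsv", "gene_id")
        io.write_matrix(self.methylation, outdir / "methylation.tsv", "probe_id")
        io.write_matrix(self.copy_number, outdir / "copy_number.tsv", "gene_id")
        self.probe_map.to_csv(outdir / "probe_map.tsv", sep="\t", index=False)
        self.gene_annot.to_csv(outdir / "gene_annot.tsv", sep="\t", index=False)
        io.write_tss(self.lnc_annot, outdir / "lncrna_tss.tsv")

    @classmethod
    def read(cls, outdir) -> "OmicsCohort":
        outdir = Path(outdir)
        return cls(
            lncrna_expr=io.read_matrix(outdir / "lncrna_expr.tsv"),
            mrna_expr=io.read_matrix(outdir / "mrna_expr.tsv"),
            methylation=io.read_matrix(outdir / "methylation.tsv"),
            probe_map=pd.read_csv(outdir / "probe_map.tsv", sep="\t", dtype=str),
            copy_number=io.read_matrix(outdir / "copy_number.tsv"),
            gene_annot=pd.read_csv(outdir / "gene_annot.tsv", sep="\t", dtype=str),
            lnc_annot=io.read_tss(outdir / "lncrna_tss.tsv"),
        )


@dataclass
class TruthTable:
    """Planted ground truth for recovery tests."""

    drivers: dict[str, int]  # lncrna_id -> +1 inducer / -1 suppressor
    driver_modules: dict[str, list[str]]  # module_id -> member genes
    confounded_pairs: list[tuple[str, str]]  # (lncrna_id, gene_id)
    essential_genes: list[str]
    prognostic: dict[str, int]  # gene_id -> hazard sign (+1 higher hazard)
    treat_up: list[str]
    treat_down: list[str]
    dataset_specific: list[str]
    peak_proximal: list[str]
    low_expressed_lncrnas: list[str] = field(default_factory=list)
    low_expressed_genes: list[str] = field(default_factory=list)
    decoy_modules: dict[str, list[str]] = field(default_factory=dict)
    driver_module_direction: dict[str, int] = field(default_factory=dict)

    def inducers(self) -> list[str]:
        return [l for l, s in self.drivers.items() if s > 0]

    def suppressors(self) -> list[str]:
        return [l for l, s in self.drivers.items() if s < 0]

    def validate(self, cohort: OmicsCohort) -> None:
        lncs = set(cohort.lncrna_expr.index)
        genes = set(cohort.mrna_expr.index)
        if set(self.inducers()) & set(self.suppressors()):
            raise ValueError("inducer and suppressor sets overlap")
        missing = set(self.drivers) - lncs
        if missing:
            raise ValueError(f"driver lncRNAs absent from cohort: {sorted(missing)}")
        for mod, members in self.driver_modules.items():
            absent = set(members) - genes
            if absent:
                raise ValueError(f"module {mod} members absent: {sorted(absent)[:5]}")
        for group in (self.essential_genes, list(self.prognostic)):
            absent = set(group) - genes
            if absent:
                raise ValueError(f"planted genes absent: {sorted(absent)[:5]}")
        for group in (self.treat_up, self.treat_down, self.peak_proximal):
            absent = set(group) - lncs
            if absent:
                raise ValueError(f"planted lncRNAs absent: {sorted(absent)[:5]}")

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["confounded_pairs"] = [list(p) for p in self.confounded_pairs]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        payload["confounded_pairs"] = [tuple(p) for p in payload["confounded_pairs"]]
        return cls(**payload)


def generate_cohort(config: SynthConfig) -> tuple[OmicsCohort, TruthTable]:
    """Generate the aligned multi-omics cohort and its truth table.

    Gene expression follows ``y = b0 - b_DM * z(meth) + b_CNV * z(cnv)
    + sum_d sign_d * b_lnc * z(lnc_d) + noise`` on a shifted scale, with the
    lncRNA terms present only for planted driver-module genes.  Driver
    lncRNAs all target all driver modules, inducers with positive sign and
    suppressors negative.
    """
    config.validate()
    rng = _rng(config, _STREAM_COHORT)
    n = config.n_samples
    samples = _ids("S", n)
    genes = _ids("G", config.n_genes)
    lncs = _ids("L", config.n_lncrnas)

    gene_chrom = [f"chr{int(c)}" for c in rng.integers(1, _N_CHROMS + 1, config.n_genes)]
    lnc_chrom = [f"chr{int(c)}" for c in rng.integers(1, _N_CHROMS + 1, config.n_lncrnas)]
    lnc_strand = np.where(rng.random(config.n_lncrnas) < 0.5, "+", "-")
    lnc_tss = rng.integers(1_000_000, _CHROM_LENGTH - 1_000_000, config.n_lncrnas)

    # ---- role allocation -------------------------------------------------
    n_drivers = config.n_driver_inducers + config.n_driver_suppressors
    if n_drivers + round(config.frac_low_expressed * config.n_lncrnas) \
            + config.n_dataset_specific > config.n_lncrnas:
        raise ValueError("not enough lncRNAs for the requested planted roles")
    lnc_order = list(rng.permutation(config.n_lncrnas))
    inducers = [lncs[i] for i in lnc_order[: config.n_driver_inducers]]
    suppressors = [
        lncs[i] for i in lnc_order[config.n_driver_inducers: n_drivers]
    ]
    n_low_l = round(config.frac_low_expressed * config.n_lncrnas)
    low_lncs = [lncs[i] for i in lnc_order[n_drivers: n_drivers + n_low_l]]
    ds_start = n_drivers + n_low_l
    dataset_specific = [
        lncs[i] for i in lnc_order[ds_start: ds_start + config.n_dataset_specific]
    ]

    sizes = rng.integers(
        config.module_size_range[0],
        config.module_size_range[1] + 1,
        config.n_driver_modules,
    )
    n_pool = int(sizes.sum())
    n_conf = round(config.frac_confounded * config.n_genes)
    n_low_g = round(config.frac_low_expressed * config.n_genes)
    if n_pool + n_conf + n_low_g + config.n_prognostic > config.n_genes:
        raise ValueError("not enough genes for the requested planted structure")
    gene_order = list(rng.permutation(config.n_genes))
    pool = [genes[i] for i in gene_order[:n_pool]]
    conf_genes = [genes[i] for i in gene_order[n_pool: n_pool + n_conf]]
    prog_start = n_pool + n_conf
    prognostic_genes = [
        genes[i] for i in gene_order[prog_start: prog_start + config.n_prognostic]
    ]
    low_start = prog_start + config.n_prognostic
    low_genes = [genes[i] for i in gene_order[low_start: low_start + n_low_g]]

    driver_modules: dict[str, list[str]] = {}
    offset = 0
    for j, size in enumerate(sizes, start=1):
        driver_modules[f"M{j:04d}"] = pool[offset: offset + int(size)]
        offset += int(size)

    n_extra_ess = max(0, config.n_essential - n_pool)
    non_pool = [g for g in genes if g not in set(pool)]
    extra_ess = [
        non_pool[i]
        for i in rng.choice(len(non_pool), size=min(n_extra_ess, len(non_pool)),
                            replace=False)
    ]
    essential_genes = sorted(set(pool) | set(extra_ess))

    # confounded pairing: each confounder-only gene borrows the locus copy
    # number of a random non-driver, non-low lncRNA
    eligible = [
        l for l in lncs
        if l not in set(inducers) | set(suppressors) | set(low_lncs)
    ]
    partners = [
        eligible[i] for i in rng.integers(0, len(eligible), size=n_conf)
    ]
    confounded_pairs = list(zip(partners, conf_genes))

    # ---- matrices --------------------------------------------------------
    lnc_cnv = rng.normal(0.0, 0.5, size=(config.n_lncrnas, n))
    rho = config.cnv_lnc_coupling
    lnc_expr = (
        5.0
        + rho * _zrow(lnc_cnv)
        + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=(config.n_lncrnas, n))
    )
    lnc_index = {l: i for i, l in enumerate(lncs)}
    for l in low_lncs:
        lnc_expr[lnc_index[l]] = rng.exponential(0.02, size=n)

    # Driver expression profiles are drawn exactly orthogonal in-sample
    # (random rotation, centered, unit sample SD): planted effects are then
    # separable by construction, so each single-lncRNA regression estimates
    # its own planted coefficient without leakage from the co-planted
    # drivers.  Real regulators would be collinear; see the methods note.
    driver_ids_all = inducers + suppressors
    if driver_ids_all:
        raw = np.column_stack(
            [np.ones(n), rng.normal(size=(n, len(driver_ids_all)))]
        )
        q, _ = np.linalg.qr(raw)
        ortho = q[:, 1:].T * np.sqrt(n - 1)  # centered, sample SD exactly 1
        for row, l in zip(ortho, driver_ids_all):
            lnc_expr[lnc_index[l]] = 5.0 + row

    cnv = rng.normal(0.0, 0.5, size=(config.n_genes, n))
    gene_index = {g: i for i, g in enumerate(genes)}
    for lnc_id, gene_id in confounded_pairs:
        cnv[gene_index[gene_id]] = lnc_cnv[lnc_index[lnc_id]]

    latent = rng.normal(size=(config.n_genes, n))
    beta_true = 1.0 / (1.0 + np.exp(-1.2 * latent))
    x_dm = _zrow(beta_true)
    x_cnv = _zrow(cnv)

    noise = rng.normal(scale=config.noise_sd, size=(config.n_genes, n))
    mrna = 5.0 - config.beta_dm_effect * x_dm + config.beta_cnv_effect * x_cnv + noise

    # Directional wiring: the first half of the driver modules is induced by
    # ALL inducers (+beta each), the second half suppressed by ALL
    # suppressors (-beta each).  Keeping the two regulator classes on
    # disjoint module halves bounds the per-gene driver count (and hence the
    # residual variance each single-lncRNA regression absorbs) while every
    # driver still touches every module of its own direction — the
    # consistency the rank-aggregation meta-analysis looks for.
    module_ids = list(driver_modules)
    n_ind_mod = int(np.ceil(len(module_ids) / 2)) if inducers else 0
    if not suppressors:
        n_ind_mod = len(module_ids)
    module_direction = {
        m: (1 if i < n_ind_mod else -1) for i, m in enumerate(module_ids)
    }
    if config.beta_lnc_effect != 0.0:
        for group, sign in ((inducers, 1), (suppressors, -1)):
            if not group:
                continue
            targets = [
                g
                for m in module_ids
                if module_direction[m] == sign
                for g in driver_modules[m]
            ]
            if not targets:
                continue
            group_z = _zrow(lnc_expr[[lnc_index[l] for l in group]])
            effect = sign * group_z.sum(axis=0)
            mrna[[gene_index[g] for g in targets]] += (
                config.beta_lnc_effect * effect
            )
    for g in low_genes:
        mrna[gene_index[g]] = rng.exponential(0.1, size=n)

    # three probes per gene, one anti-correlated "true" probe
    true_slot = rng.integers(1, 4, size=config.n_genes)
    probe_rows = []
    probe_ids = []
    probe_gene = []
    decoy = 1.0 / (1.0 + np.exp(-1.2 * rng.normal(size=(config.n_genes, 2, n))))
    for gi, g in enumerate(genes):
        d_iter = iter(range(2))
        for slot in (1, 2, 3):
            probe_ids.append(f"{g}_p{slot}")
            probe_gene.append(g)
            if slot == true_slot[gi]:
                probe_rows.append(beta_true[gi])
            else:
                probe_rows.append(decoy[gi, next(d_iter)])
    methylation = pd.DataFrame(
        np.vstack(probe_rows), index=pd.Index(probe_ids, name="probe_id"),
        columns=samples,
    )

    cohort = OmicsCohort(
        lncrna_expr=pd.DataFrame(lnc_expr, index=pd.Index(lncs, name="lncrna_id"),
                                 columns=samples),
        mrna_expr=pd.DataFrame(mrna, index=pd.Index(genes, name="gene_id"),
                               columns=samples),
        methylation=methylation,
        probe_map=pd.DataFrame({"probe_id": probe_ids, "gene_id": probe_gene}),
        copy_number=pd.DataFrame(cnv, index=pd.Index(genes, name="gene_id"),
                                 columns=samples),
        gene_annot=pd.DataFrame({"gene_id": genes, "chrom": gene_chrom}),
        lnc_annot=pd.DataFrame(
            {
                "lncrna_id": lncs,
                "chrom": lnc_chrom,
                "strand": lnc_strand,
                "tss_position": lnc_tss,
            }
        ),
    )
    truth = TruthTable(
        drivers={**{l: 1 for l in inducers}, **{l: -1 for l in suppressors}},
        driver_modules=driver_modules,
        confounded_pairs=confounded_pairs,
        essential_genes=essential_genes,
        prognostic={
            g: (1 if i % 2 == 0 else -1) for i, g in enumerate(prognostic_genes)
        },
        treat_up=suppressors[:],
        treat_down=inducers[:],
        dataset_specific=dataset_specific,
        peak_proximal=suppressors[: config.n_peak_proximal],
        low_expressed_lncrnas=low_lncs,
        low_expressed_genes=low_genes,
        driver_module_direction=module_direction,
    )
    truth.validate(cohort)
    return cohort, truth


def generate_modules(
    config: SynthConfig, truth: TruthTable, cohort: OmicsCohort
) -> ModuleSet:
    """Planted driver modules plus syntenic / low-density / null decoys.

    Driver modules get densities drawn from ``density_range`` and are
    non-syntenic by construction; syntenic decoys draw all members from one
    chromosome (any density), low-density decoys get density < 0.5, and the
    remaining decoys are random high-density gene sets with no planted
    signal.  Decoy ids are recorded on ``truth.decoy_modules``.
    """
    lo, hi = config.module_size_range
    if hi > len(cohort.mrna_expr.index):
        raise ValueError("module_size_range exceeds the number of genes")
    rng = _rng(config, _STREAM_MODULES)
    genes = list(cohort.mrna_expr.index)
    gene_chrom = dict(zip(cohort.gene_annot["gene_id"], cohort.gene_annot["chrom"]))
    pool = {g for members in truth.driver_modules.values() for g in members}
    background = [g for g in genes if g not in pool]
    d_lo, d_hi = config.density_range

    modules = []
    for mod_id, members in truth.driver_modules.items():
        density = float(rng.uniform(d_lo, d_hi))
        mod = CoessentialModule(mod_id, members, density)
        if len(mod.chromosomes(gene_chrom)) <= 1:  # pragma: no cover - tiny odds
            swap = rng.choice(len(background))
            mod.members[-1] = background[int(swap)]
        modules.append(mod)

    n_decoys = config.n_modules - config.n_driver_modules
    n_syn = round(config.frac_syntenic_decoys * n_decoys)
    n_low = round(config.frac_lowdensity_decoys * n_decoys)
    n_syn = min(n_syn, n_decoys)
    n_low = min(n_low, n_decoys - n_syn)
    next_id = config.n_driver_modules + 1
    decoys: dict[str, list[str]] = {"syntenic": [], "low_density": [], "null": []}

    by_chrom: dict[str, list[str]] = {}
    for g in background:
        by_chrom.setdefault(gene_chrom[g], []).append(g)
    roomy_chroms = sorted(c for c, gs in by_chrom.items() if len(gs) >= lo)
    if n_syn and not roomy_chroms:
        raise ValueError("no chromosome holds enough genes for a syntenic decoy")

    for _ in range(n_syn):
        chrom = roomy_chroms[int(rng.choice(len(roomy_chroms)))]
        size = int(rng.integers(lo, min(hi, len(by_chrom[chrom])) + 1))
        members = [
            by_chrom[chrom][i]
            for i in rng.choice(len(by_chrom[chrom]), size=size, replace=False)
        ]
        mod_id = f"M{next_id:04d}"
        modules.append(
            CoessentialModule(mod_id, members, float(rng.uniform(d_lo, d_hi)))
        )
        decoys["syntenic"].append(mod_id)
        next_id += 1

    def _random_members(size: int) -> list[str]:
        while True:
            members = [
                background[i]
                for i in rng.choice(len(background), size=size, replace=False)
            ]
            if len({gene_chrom[m] for m in members}) > 1:
                return members

    for _ in range(n_low):
        size = int(rng.integers(lo, hi + 1))
        mod_id = f"M{next_id:04d}"
        density = float(rng.uniform(0.2, min(0.45, max(0.21, d_lo - 0.05))))
        modules.append(CoessentialModule(mod_id, _random_members(size), density))
        decoys["low_density"].append(mod_id)
        next_id += 1

    for _ in range(n_decoys - n_syn - n_low):
        size = int(rng.integers(lo, hi + 1))
        mod_id = f"M{next_id:04d}"
        modules.append(
            CoessentialModule(mod_id, _random_members(size), float(rng.uniform(d_lo, d_hi)))
        )
        decoys["null"].append(mod_id)
        next_id += 1

    truth.decoy_modules = decoys
    return ModuleSet(modules)


_PROLIF_HALLMARK = (
    "HALLMARK_MYC_TARGETS_V1",
    "HALLMARK_MYC_TARGETS_V2",
    "HALLMARK_E2F_TARGETS",
    "HALLMARK_G2M_CHECKPOINT",
    "HALLMARK_MITOTIC_SPINDLE",
)


def generate_genesets(
    config: SynthConfig,
    truth: TruthTable,
    n_other_hallmark: int = 15,
    n_other_kegg: int = 10,
    set_size: int = 100,
    pool_fraction: float = 0.8,
) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Hallmark-like and pathway-like collections with planted overlap.

    Proliferation-named sets draw ``pool_fraction`` of their members from
    the planted driver-module gene pool (so driver modules annotate as
    proliferation-linked); the remaining sets are random background gene
    sets spread over the other seven broad categories.
    """
    rng = _rng(config, _STREAM_GENESETS)
    genes = _ids("G", config.n_genes)
    pool = sorted({g for members in truth.driver_modules.values() for g in members})
    background = [g for g in genes if g not in set(pool)]
    set_size = min(set_size, len(background))

    def _planted_set() -> list[str]:
        n_from_pool = min(len(pool), round(pool_fraction * set_size))
        chosen = [pool[i] for i in rng.choice(len(pool), n_from_pool, replace=False)]
        n_bg = min(set_size - n_from_pool, len(background))
        chosen += [
            background[i] for i in rng.choice(len(background), n_bg, replace=False)
        ]
        return chosen

    def _background_set() -> list[str]:
        return [
            background[i] for i in rng.choice(len(background), set_size, replace=False)
        ]

    hallmark_sets = {name: _planted_set() for name in _PROLIF_HALLMARK}
    categories = {name: "proliferation" for name in _PROLIF_HALLMARK}
    other_categories = [c for c in HALLMARK_CATEGORIES if c != "proliferation"]
    for i in range(n_other_hallmark):
        name = f"HALLMARK_BACKGROUND_{i + 1:02d}"
        hallmark_sets[name] = _background_set()
        categories[name] = other_categories[i % len(other_categories)]
    hallmark = GeneSetCollection(hallmark_sets, label="hallmark", categories=categories)

    kegg_sets = {"KEGG_CELL_CYCLE": _planted_set()}
    for i in range(n_other_kegg):
        kegg_sets[f"KEGG_PATHWAY_{i + 1:02d}"] = _background_set()
    kegg = GeneSetCollection(kegg_sets, label="kegg")
    return hallmark, kegg


def generate_treatment_counts(
    config: SynthConfig, truth: TruthTable
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Negative-binomial treated/control count matrices over all lncRNAs.

    Planted consistently-up/-down lncRNAs carry a ``treatment_log2fc`` shift
    in ``ceil(treatment_consistency * n_datasets)`` randomly chosen datasets;
    dataset-specific decoys are shifted in exactly one dataset.
    """
    rng = _rng(config, _STREAM_TREATMENT)
    lncs = _ids("L", config.n_lncrnas)
    n_ds = config.n_treatment_datasets
    n_consistent = int(np.ceil(config.treatment_consistency * n_ds))
    base_mu = np.exp(rng.normal(config.nb_mean_log, config.nb_mean_sd,
                                size=config.n_lncrnas))
    shift = np.zeros((n_ds, config.n_lncrnas))
    lnc_pos = {l: i for i, l in enumerate(lncs)}
    for l in truth.treat_up:
        ds = rng.choice(n_ds, size=n_consistent, replace=False)
        shift[ds, lnc_pos[l]] = config.treatment_log2fc
    for l in truth.treat_down:
        ds = rng.choice(n_ds, size=n_consistent, replace=False)
        shift[ds, lnc_pos[l]] = -config.treatment_log2fc
    for j, l in enumerate(truth.dataset_specific):
        ds = int(rng.integers(0, n_ds))
        shift[ds, lnc_pos[l]] = config.treatment_log2fc * (1 if j % 2 == 0 else -1)

    r = 1.0 / config.nb_dispersion
    reps = config.n_treatment_replicates

    def _nb(mu: np.ndarray) -> np.ndarray:
        p = r / (r + mu)
        return rng.negative_binomial(r, p[:, None], size=(mu.size, reps))

    datasets = []
    for d in range(n_ds):
        mu_t = base_mu * np.exp2(shift[d])
        treated = pd.DataFrame(
            _nb(mu_t), index=pd.Index(lncs, name="lncrna_id"),
            columns=[f"T{k + 1}" for k in range(reps)],
        )
        control = pd.DataFrame(
            _nb(base_mu), index=pd.Index(lncs, name="lncrna_id"),
            columns=[f"C{k + 1}" for k in range(reps)],
        )
        datasets.append((treated, control))
    return datasets


def generate_survival(
    config: SynthConfig, truth: TruthTable, expression: pd.DataFrame
) -> pd.DataFrame:
    """Exponential survival with log-hazard linear in planted gene z-scores.

    ``hazard = baseline * exp(sum_g sign_g * hazard_log_hr * z_g)`` over the
    planted prognostic genes; censoring is an independent exponential
    calibrated so roughly ``censor_rate`` of samples are censored
    (``censor_rate = 0`` means every event is observed).
    """
    rng = _rng(config, _STREAM_SURVIVAL)
    samples = list(expression.columns)
    eta = np.zeros(len(samples))
    for gene, sign in truth.prognostic.items():
        if gene not in expression.index:
            continue
        z = _zrow(expression.loc[gene].to_numpy(dtype=float)[None, :])[0]
        eta += sign * config.hazard_log_hr * z
    lam = config.baseline_hazard * np.exp(eta)
    event_times = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        lam_c = config.baseline_hazard * config.censor_rate / (1 - config.censor_rate)
        censor_times = rng.exponential(1.0 / lam_c, size=len(samples))
    else:
        censor_times = np.full(len(samples), np.inf)
    observed = event_times <= censor_times
    return pd.DataFrame(
        {
            "sample_id": samples,
            "time": np.minimum(event_times, censor_times),
            "event": observed.astype(int),
        }
    )


def generate_peaks_and_tss(
    config: SynthConfig, truth: TruthTable, cohort: OmicsCohort
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Per-dataset peak sets (BED convention) and the lncRNA TSS table.

    Planted proximal lncRNAs receive a peak within 80% of the proximity
    window of their TSS in ``ceil(peak_window_frac * n_peak_datasets)``
    datasets; every dataset also carries uniform background peaks.
    """
    rng = _rng(config, _STREAM_PEAKS)
    tss = cohort.lnc_annot.copy()
    tss_pos = dict(zip(tss["lncrna_id"], tss["tss_position"]))
    tss_chrom = dict(zip(tss["lncrna_id"], tss["chrom"]))
    n_ds = config.n_peak_datasets
    n_hit = int(np.ceil(config.peak_window_frac * n_ds))
    half = config.peak_halfwidth
    jitter = int(0.8 * config.tss_window)

    planted: dict[int, list[tuple[str, int, int]]] = {d: [] for d in range(n_ds)}
    for l in truth.peak_proximal:
        ds = rng.choice(n_ds, size=n_hit, replace=False)
        for d in ds:
            center = tss_pos[l] - 1 + int(rng.integers(-jitter, jitter + 1))
            start = max(0, center - half)
            planted[int(d)].append((tss_chrom[l], start, center + half))

    peaksets = []
    for d in range(n_ds):
        chroms = [
            f"chr{int(c)}" for c in rng.integers(1, _N_CHROMS + 1,
                                                 config.n_background_peaks)
        ]
        starts = rng.integers(0, _CHROM_LENGTH - 2 * half,
                              config.n_background_peaks)
        rows = planted[d] + list(zip(chroms, starts, starts + 2 * half))
        peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        peaks = peaks.sort_values(["chrom", "start"], kind="mergesort")
        peaksets.append(peaks.reset_index(drop=True))
    return peaksets, tss


def write_all(config: SynthConfig, outdir) -> None:
    """Generate every pipeline input and write it under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, truth = generate_cohort(config)
    cohort.write(outdir)
    modules = generate_modules(config, truth, cohort)
    modules.to_tsv(outdir / "modules.tsv")
    hallmark, kegg = generate_genesets(config, truth)
    hallmark.to_gmt(outdir / "hallmark.gmt")
    kegg.to_gmt(outdir / "kegg.gmt")
    pd.Series(truth.essential_genes, name="gene_id").to_csv(
        outdir / "essential_genes.txt", index=False, header=False
    )
    treatment = generate_treatment_counts(config, truth)
    tdir = outdir / "treatment"
    tdir.mkdir(exist_ok=True)
    for d, (treated, control) in enumerate(treatment, start=1):
        io.write_matrix(treated, tdir / f"dataset{d:02d}_treated.tsv", "lncrna_id")
        io.write_matrix(control, tdir / f"dataset{d:02d}_control.tsv", "lncrna_id")
    surv = generate_survival(config, truth, cohort.mrna_expr)
    io.write_survival(surv, outdir / "survival.tsv")
    peaksets, tss = generate_peaks_and_tss(config, truth, cohort)
    pdir = outdir / "peaks"
    pdir.mkdir(exist_ok=True)
    for d, peaks in enumerate(peaksets, start=1):
        io.write_bed(peaks, pdir / f"dataset{d:02d}.bed")
    io.write_tss(tss, outdir / "lncrna_tss.tsv")
    truth.to_json(outdir / "truth.json")
    config.to_yaml(outdir / "config.yaml")
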