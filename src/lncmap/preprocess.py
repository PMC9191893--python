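"""Feature filtering, representative-probe selection, and standardization.

The filtering rules mirror common practice for pan-cancer expression panels:

* mRNAs are kept when normalized expression is >= 1 in at least 75% of
  samples (inclusive boundary);
* lncRNAs are kept when the median of normalized expression is > 0 AND the
  90th percentile is > 0.1 (both on the input scale as given);
* when several promoter methylation probes map to one gene, the probe with
  the strongest NEGATIVE Spearman correlation to that gene's expression is
  kept (the most-negative probe wins even if it is non-negative);
* features are z-scored with the sample (n-1) standard deviation.

Percentiles use numpy's linear-interpolation definition.  Missing values are
not supported: inputs containing NaN are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


def _check_no_missing(matrix: pd.DataFrame, name: str) -> None:
    if matrix.isna().to_numpy().any():
        raise ValueError(
            f"{name} contains missing values; imputation is not supported — "
            "clean the input first"
        )


def filter_mrna(
    mrna_expr: pd.DataFrame, min_value: float = 1.0, min_fraction: float = 0.75
) -> pd.DataFrame:
    """Keep genes with expression >= min_value in >= min_fraction of samples."""
    if mrna_expr.shape[0] == 0 or mrna_expr.shape[1] == 0:
        raise ValueError("mrna_expr is empty")
    _check_no_missing(mrna_expr, "mrna_expr")
    frac = (mrna_expr.to_numpy() >= min_value).mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        warnings.warn("filter_mrna removed every gene", stacklevel=2)
    return mrna_expr.loc[keep]


def filter_lncrna(lncrna_expr: pd.DataFrame) -> pd.DataFrame:
    """Keep lncRNAs with median > 0 and 90th percentile > 0.1."""
    if lncrna_expr.shape[0] == 0 or lncrna_expr.shape[1] == 0:
        raise ValueError("lncrna_expr is empty")
    _check_no_missing(lncrna_expr, "lncrna_expr")
    values = lncrna_expr.to_numpy(dtype=float)
    median = np.percentile(values, 50, axis=1)
    p90 = np.percentile(values, 90, axis=1)
    keep = (median > 0) & (p90 > 0.1)
    if not keep.any():
        warnings.warn("filter_lncrna removed every lncRNA", stacklevel=2)
    return lncrna_expr.loc[keep]


def select_representative_probe(
    methylation: pd.DataFrame,
    probe_map: pd.DataFrame,
    mrna_expr: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """One methylation probe per gene: the most negative Spearman rho wins.

    Parameters
    ----------
    methylation : probe x sample beta-value matrix.
    probe_map : DataFrame with columns ``probe_id`` and ``gene_id``.
    mrna_expr : gene x sample expression matrix (same samples).

    Returns
    -------
    (gene x sample beta-value matrix of selected probes, gene -> probe map).
    Genes absent from ``mrna_expr`` are dropped with a warning.  Probe-score
    ties break by lexicographic probe id, so the choice is independent of
    probe input order.
    """
    _check_no_missing(methylation, "methylation")
    samples = mrna_expr.columns
    meth = methylation[samples]
    # Spearman = Pearson on average ranks; vectorized row-wise.
    meth_rank = meth.rank(axis=1).to_numpy(dtype=float)
    expr_rank = mrna_expr.rank(axis=1).to_numpy(dtype=float)

    def _standardize(r: np.ndarray) -> np.ndarray:
        r = r - r.mean(axis=1, keepdims=True)
        sd = r.std(axis=1, keepdims=True)
        sd[sd == 0] = np.inf  # constant rows get rho 0 against everything
        return r / sd

    meth_z = _standardize(meth_rank)
    expr_z = _standardize(expr_rank)
    probe_pos = {p: i for i, p in enumerate(meth.index)}
    gene_pos = {g: i for i, g in enumerate(mrna_expr.index)}

    chosen: dict[str, str] = {}
    dropped = []
    for gene_id, grp in probe_map.groupby("gene_id", sort=True):
        if gene_id not in gene_pos:
            dropped.append(gene_id)
            continue
        gz = expr_z[gene_pos[gene_id]]
        best: Optional[tuple[float, str]] = None
        for probe_id in grp["probe_id"]:
            if probe_id not in probe_pos:
                continue
            rho = float(np.mean(meth_z[probe_pos[probe_id]] * gz))
            key = (rho, str(probe_id))
            if best is None or key < best:
                best = key
        if best is not None:
            chosen[str(gene_id)] = best[1]
    if dropped:
        warnings.warn(
            f"{len(dropped)} mapped genes absent from expression; their probes "
            "were dropped",
            stacklevel=2,
        )
    gene_ids = list(chosen)
    selected = meth.loc[[chosen[g] for g in gene_ids]].copy()
    selected.index = pd.Index(gene_ids, name="gene_id")
    return selected, pd.Series(chosen, name="probe_id")


def zscore(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Row-wise z-scores; zero-variance features are dropped with a warning."""
    _check_no_missing(matrix, "matrix")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=ddof)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"zscore dropped {int((~keep).sum())} zero-variance features",
            stacklevel=2,
        )
    values = values[keep]
    mean = values.mean(axis=1, keepdims=True)
    sd_kept = sd[keep][:, None]
    return pd.DataFrame(
        (values - mean) / sd_kept, index=matrix.index[keep], columns=matrix.columns
    )


@dataclass
class PreparedCohort:
    """Sample-aligned, filtered, z-scored matrices ready for regression."""

    lncrna_z: pd.DataFrame  # lncRNA x sample
    mrna_z: pd.DataFrame  # gene x sample
    methylation_z: pd.DataFrame  # gene x sample (selected probe, z-scored)
    copy_number_z: pd.DataFrame  # gene x sample
    probe_choice: pd.Series  # gene -> selected probe id
    gene_annot: Optional[pd.DataFrame] = None  # gene_id, chrom
    lnc_annot: Optional[pd.DataFrame] = None  # lncrna_id, chrom, strand, tss

    @property
    def samples(self) -> pd.Index:
        return self.mrna_z.columns


def prepare_cohort(cohort) -> PreparedCohort:
    """Run the full preprocessing policy on an :class:`OmicsCohort`.

    Filters both expression matrices, selects representative methylation
    probes against the filtered mRNA matrix, aligns every matrix on the
    common ordered sample set, and z-scores all four tracks.
    """
    samples = cohort.mrna_expr.columns
    for name, m in [
        ("lncrna_expr", cohort.lncrna_expr),
        ("methylation", cohort.methylation),
        ("copy_number", cohort.copy_number),
    ]:
        if not samples.equals(m.columns):
            common = samples.intersection(m.columns)
            if len(common) == 0:
                raise ValueError(f"{name} shares no samples with mrna_expr")
            samples = common
    mrna = filter_mrna(cohort.mrna_expr[samples])
    lnc = filter_lncrna(cohort.lncrna_expr[samples])
    meth_beta, probe_choice = select_representative_probe(
        cohort.methylation[samples], cohort.probe_map, mrna
    )
    cnv = cohort.copy_number[samples]
    _check_no_missing(cnv, "copy_number")
    return PreparedCohort(
        lncrna_z=zscore(lnc),
        mrna_z=zscore(mrna),
        methylation_z=zscore(meth_beta),
        copy_number_z=zscore(cnv),
        probe_choice=probe_choice,
        gene_annot=getattr(cohort, "gene_annot", None),
        lnc_annot=getattr(cohort, "lnc_annot", None),
    )
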