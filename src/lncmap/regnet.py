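"""Confounder-adjusted lncRNA-mRNA association networks.

For every (lncRNA l, gene g) pair the model is the four-term OLS regression

    Y_s = b0 + b_DM * xDM_s + b_CNV * xCNV_s + b_lnc * xlnc_s ,  s = 1..n

on z-scored tracks, where xDM is the gene's selected promoter-methylation
probe and xCNV its copy-number profile.  The lncRNA term therefore captures
co-expression not explained by the two genomic confounders; ``p_lnc`` is the
two-sided t-test on b_lnc with n - 4 degrees of freedom.  Significant pairs
are selected at BH-adjusted p below a network-wide cutoff (default 1e-3),
with the BH family being ALL fitted pairs of the dataset.

``build_network`` fits every pair via the Frisch-Waugh-Lovell decomposition
(residualize the gene and all lncRNAs on [1, xDM, xCNV] once per gene), which
is algebraically identical to the per-pair normal equations solved by
``fit_pair``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import hypergeom_upper_tail
from .multitest import bh_adjust
from .preprocess import PreparedCohort

FLAG_OK = "ok"
FLAG_COLLINEAR = "collinear"

# relative tolerance on the residual variance of a predictor before the
# design is treated as rank-deficient
_RANK_TOL = 1e-10


@dataclass
class PairFit:
    """OLS estimates for a single (lncRNA, gene) pair."""

    beta0: float
    beta_dm: float
    beta_cnv: float
    beta_lnc: float
    se_lnc: float
    t_lnc: float
    p_lnc: float
    n_samples: int
    flag: str = FLAG_OK


def fit_pair(y, x_dm, x_cnv, x_lnc) -> PairFit:
    """Fit the four-term regression for one pair.

    A rank-deficient design (e.g. x_cnv identical to x_dm) yields a flagged
    record with ``p_lnc = 1`` and flag ``"collinear"`` rather than an
    exception, so degenerate features cannot crash a network build.
    """
    y = np.asarray(y, dtype=float)
    x_dm = np.asarray(x_dm, dtype=float)
    x_cnv = np.asarray(x_cnv, dtype=float)
    x_lnc = np.asarray(x_lnc, dtype=float)
    n = y.shape[0]
    if not (x_dm.shape[0] == x_cnv.shape[0] == x_lnc.shape[0] == n):
        raise ValueError("all four vectors must have equal length")
    if n < 5:
        raise ValueError(f"need n >= 5 samples (df = n - 4 >= 1), got {n}")
    X = np.column_stack([np.ones(n), x_dm, x_cnv, x_lnc])
    if np.linalg.matrix_rank(X) < 4:
        return PairFit(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 1.0, n, FLAG_COLLINEAR
        )
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - 4)
    cov = sigma2 * np.linalg.inv(XtX)
    se = float(np.sqrt(cov[3, 3]))
    if se == 0.0:
        t = np.inf if beta[3] != 0 else 0.0
        p = 0.0 if beta[3] != 0 else 1.0
    else:
        t = float(beta[3] / se)
        p = 2.0 * float(stats.t.sf(abs(t), n - 4))
    return PairFit(*(float(b) for b in beta), se, t, p, n)


class AssociationNetwork:
    """Fitted lncRNA-mRNA pairs with their significance flags.

    ``table`` has one row per (lncRNA, gene) pair with columns
    ``lncrna_id, gene_id, beta0, beta_dm, beta_cnv, beta_lnc, p_lnc,
    adj_p_lnc, n_samples, flag, significant``.
    """

    def __init__(self, table: pd.DataFrame, alpha: float = 1e-3):
        if table.duplicated(["lncrna_id", "gene_id"]).any():
            raise ValueError("duplicate (lncrna, gene) pairs in network table")
        self.table = table.reset_index(drop=True)
        self.alpha = float(alpha)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def lncrna_ids(self) -> list[str]:
        return list(pd.unique(self.table["lncrna_id"]))

    @property
    def gene_ids(self) -> list[str]:
        return list(pd.unique(self.table["gene_id"]))

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def partners(self, lncrna_id: str, sign: Optional[int] = None) -> list[str]:
        """Significant partner genes of one lncRNA, optionally by coefficient sign."""
        sub = self.table[
            (self.table["lncrna_id"] == lncrna_id) & self.table["significant"]
        ]
        if sign is not None:
            sub = sub[np.sign(sub["beta_lnc"]) == sign]
        return sub["gene_id"].tolist()

    def coefficients(self, lncrna_id: str) -> pd.Series:
        """All fitted b_lnc of one lncRNA, indexed by gene."""
        sub = self.table[self.table["lncrna_id"] == lncrna_id]
        return pd.Series(
            sub["beta_lnc"].to_numpy(), index=sub["gene_id"].astype(str), name=lncrna_id
        )

    def coefficient_matrix(self) -> pd.DataFrame:
        """lncRNA x gene matrix of b_lnc (NaN where a pair was not fitted)."""
        return self.table.pivot(index="lncrna_id", columns="gene_id", values="beta_lnc")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, alpha: float = 1e-3) -> "AssociationNetwork":
        table = pd.read_csv(
            path, sep="\t", dtype={"lncrna_id": str, "gene_id": str}
        )
        return cls(table, alpha=alpha)


def build_network(
    prepared: PreparedCohort,
    alpha: float = 1e-3,
    exclude_cis: bool = False,
) -> AssociationNetwork:
    """Fit all (lncRNA, gene) pairs and apply the network-wide BH cutoff.

    Genes lacking a methylation or copy-number track are skipped and counted
    in ``network.skip_report``.  With ``exclude_cis`` and chromosome
    annotations available, same-chromosome pairs are excluded (off by
    default; whether cis pairs belong in the network is left to the caller).
    """
    L = prepared.lncrna_z
    Y = prepared.mrna_z
    genes = [
        g
        for g in Y.index
        if g in prepared.methylation_z.index and g in prepared.copy_number_z.index
    ]
    skip_report = {
        "missing_covariate_track": sorted(set(Y.index) - set(genes)),
        "collinear_pairs": 0,
    }
    n = Y.shape[1]
    p = L.shape[0]
    if p == 0 or len(genes) == 0:
        empty = pd.DataFrame(
            columns=[
                "lncrna_id", "gene_id", "beta0", "beta_dm", "beta_cnv",
                "beta_lnc", "p_lnc", "adj_p_lnc", "n_samples", "flag",
                "significant",
            ]
        )
        net = AssociationNetwork(empty, alpha=alpha)
        net.skip_report = skip_report
        return net

    lnc_chrom = gene_chrom = None
    if exclude_cis:
        if prepared.lnc_annot is None or prepared.gene_annot is None:
            raise ValueError("exclude_cis requires chromosome annotations")
        lnc_chrom = prepared.lnc_annot.set_index("lncrna_id")["chrom"]
        gene_chrom = prepared.gene_annot.set_index("gene_id")["chrom"]

    Lm = np.ascontiguousarray(L.to_numpy(dtype=float).T)  # n x p
    df_resid = n - 4

    blocks = []
    for g in genes:
        y = Y.loc[g].to_numpy(dtype=float)
        x0 = np.column_stack(
            [
                np.ones(n),
                prepared.methylation_z.loc[g].to_numpy(dtype=float),
                prepared.copy_number_z.loc[g].to_numpy(dtype=float),
            ]
        )
        G = x0.T @ x0
        try:
            Ginv = np.linalg.inv(G)
        except np.linalg.LinAlgError:
            Ginv = None
        if Ginv is None or np.linalg.cond(G) > 1 / _RANK_TOL:
            # degenerate confounder design: flag every pair of this gene
            block = _flagged_block(g, L.index, n)
            blocks.append(block)
            skip_report["collinear_pairs"] += p
            continue
        gamma0 = Ginv @ (x0.T @ y)  # 3-vector, confounder-only fit
        r_y = y - x0 @ gamma0
        C = Ginv @ (x0.T @ Lm)  # 3 x p
        R = Lm - x0 @ C  # n x p residualized lncRNAs
        d = np.einsum("ij,ij->j", R, R)
        ok = d > _RANK_TOL * n
        beta = np.zeros(p)
        np.divide(R.T @ r_y, d, out=beta, where=ok)
        rss = float(r_y @ r_y) - beta**2 * d
        sigma2 = np.maximum(rss, 0.0) / df_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sigma2 / d)
            tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
        # recover the full coefficient vector: gamma = gamma0 - C * beta
        gammas = gamma0[:, None] - C * beta
        pvals[~ok] = 1.0
        beta[~ok] = np.nan
        gammas[:, ~ok] = np.nan
        skip_report["collinear_pairs"] += int((~ok).sum())
        block = pd.DataFrame(
            {
                "lncrna_id": L.index,
                "gene_id": g,
                "beta0": gammas[0],
                "beta_dm": gammas[1],
                "beta_cnv": gammas[2],
                "beta_lnc": beta,
                "p_lnc": pvals,
                "n_samples": n,
                "flag": np.where(ok, FLAG_OK, FLAG_COLLINEAR),
            }
        )
        blocks.append(block)

    table = pd.concat(blocks, ignore_index=True)
    if exclude_cis:
        same = (
            table["lncrna_id"].map(lnc_chrom).to_numpy()
            == table["gene_id"].map(gene_chrom).to_numpy()
        )
        table = table[~same].reset_index(drop=True)
    table["adj_p_lnc"] = bh_adjust(table["p_lnc"].to_numpy())
    table["significant"] = (table["adj_p_lnc"] < alpha) & (table["flag"] == FLAG_OK)
    table["lncrna_id"] = table["lncrna_id"].astype(str)
    table["gene_id"] = table["gene_id"].astype(str)
    net = AssociationNetwork(table, alpha=alpha)
    net.skip_report = skip_report
    return net


def _flagged_block(gene_id, lnc_index, n) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna_id": lnc_index,
            "gene_id": gene_id,
            "beta0": np.nan,
            "beta_dm": np.nan,
            "beta_cnv": np.nan,
            "beta_lnc": np.nan,
            "p_lnc": 1.0,
            "n_samples": n,
            "flag": FLAG_COLLINEAR,
        }
    )


CLASS_POSITIVE = "positive-enriched"
CLASS_NEGATIVE = "negative-enriched"
CLASS_BOTH = "both"
CLASS_NEITHER = "neither"


def classify_essential(
    network: AssociationNetwork,
    essential_genes: Iterable[str],
    alpha: float = 1e-10,
) -> pd.DataFrame:
    """Classify each lncRNA by essential-gene enrichment of its partners.

    Two one-sided hypergeometric tests per lncRNA: overlap of its significant
    POSITIVE partners (b_lnc > 0) with the essential genes, and likewise for
    the NEGATIVE partners, against the universe of genes fitted for that
    lncRNA.  BH runs over all (lncRNA x direction) tests; classes follow from
    which adjusted tests pass ``alpha``.
    """
    essential = set(map(str, essential_genes))
    tested_universe = set(network.gene_ids)
    outside = essential - tested_universe
    if outside:
        warnings.warn(
            f"{len(outside)} essential genes outside the tested universe were "
            "dropped",
            stacklevel=2,
        )
        essential &= tested_universe

    tbl = network.table
    rows = []
    for lnc, sub in tbl.groupby("lncrna_id", sort=True):
        fitted = sub[sub["flag"] == FLAG_OK]
        universe = set(fitted["gene_id"])
        ess_in_universe = essential & universe
        sig = fitted[fitted["significant"]]
        pos = set(sig.loc[sig["beta_lnc"] > 0, "gene_id"])
        neg = set(sig.loc[sig["beta_lnc"] < 0, "gene_id"])
        p_pos = hypergeom_upper_tail(
            len(pos & ess_in_universe), len(universe), len(ess_in_universe), len(pos)
        )
        p_neg = hypergeom_upper_tail(
            len(neg & ess_in_universe), len(universe), len(ess_in_universe), len(neg)
        )
        rows.append(
            (
                str(lnc), len(pos), len(neg),
                len(pos & ess_in_universe), len(neg & ess_in_universe),
                p_pos, p_neg,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "lncrna_id", "n_sig_pos", "n_sig_neg", "overlap_pos", "overlap_neg",
            "p_pos", "p_neg",
        ],
    )
    flat = bh_adjust(np.concatenate([out["p_pos"], out["p_neg"]]))
    out["adj_p_pos"] = flat[: len(out)]
    out["adj_p_neg"] = flat[len(out):]
    pos_hit = out["adj_p_pos"] < alpha
    neg_hit = out["adj_p_neg"] < alpha
    out["essential_class"] = np.select(
        [pos_hit & neg_hit, pos_hit, neg_hit],
        [CLASS_BOTH, CLASS_POSITIVE, CLASS_NEGATIVE],
        default=CLASS_NEITHER,
    )
    return out
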