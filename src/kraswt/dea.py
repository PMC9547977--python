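"""Negative-binomial Wald differential expression with a batch covariate.

The model is a per-gene NB GLM with log link and library-size offsets:

    K_gj ~ NB(mu_gj, alpha_g),  Var = mu + alpha * mu^2
    log mu_gj = log s_j + x_j' beta_g,      x_j = (1, batch_j, group_j)

fitted by iteratively reweighted least squares, vectorized across genes.
Size factors are median-of-ratios.  Dispersions are per-gene method-of-
moments estimates shrunk toward a log-linear mean-dispersion trend; this
deliberately simplifies the full empirical-Bayes machinery of dedicated
DE packages while preserving the calibration and power behavior that the
test suite checks.  The group coefficient codes mutant = 0, wildtype = 1,
so positive log2 fold changes mean higher expression in KRAS-wildtype
samples.  Wald z = beta / se with a two-tailed normal p-value and BH
adjustment across tested genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .core_io import ExpressionMatrix
from .stats import bh_adjust, spearman, wilcoxon_ranksum, wilcoxon_signedrank

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)
MAX_IRLS_ITER = 100
DEVIANCE_RTOL = 1e-8


def prefilter_genes(counts: ExpressionMatrix) -> list[str]:
    """Genes with a non-zero count in at least half of the samples
    (inclusive at exactly half for even n)."""
    vals = counts.values.to_numpy()
    n = vals.shape[1]
    need = int(np.ceil(n / 2))
    keep = (vals > 0).sum(axis=1) >= need
    return list(counts.values.index[keep])


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1."""
    vals = counts.values.to_numpy(dtype=float)
    all_pos = (vals > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene with non-zero counts in every sample; consider a "
            "pseudo-reference on a filtered matrix")
    sub = vals[all_pos]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    s = np.exp(np.median(ratios, axis=0))
    s = s / np.exp(np.log(s).mean())
    return pd.Series(s, index=counts.values.columns, name="size_factor")


@dataclass
class DispersionFit:
    """Per-gene raw, trend and final (shrunk) NB dispersions."""

    raw: pd.Series
    trend: pd.Series
    final: pd.Series
    trend_coef: tuple[float, float] = (0.0, 0.0)  # intercept, slope on log mean


def estimate_dispersions(norm_counts: np.ndarray, genes: list[str],
                         shrinkage: float = 0.5,
                         min_disp: float = 1e-8,
                         max_disp: float = 10.0) -> DispersionFit:
    """Method-of-moments dispersions with log-linear trend shrinkage.

    alpha_raw = (s^2 - mean) / mean^2 on size-factor-normalized counts;
    the trend is an OLS fit of log alpha on log mean; the final value
    interpolates raw and trend on the log scale with weight ``shrinkage``
    toward the trend.
    """
    mean = norm_counts.mean(axis=1)
    var = norm_counts.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mean) / np.maximum(mean, 1e-12) ** 2
    raw = np.clip(raw, min_disp, max_disp)
    ok = (mean > 0) & (raw > min_disp * 1.01)
    if ok.sum() >= 10:
        x = np.log(mean[ok])
        y = np.log(raw[ok])
        slope, intercept = np.polyfit(x, y, 1)
    else:  # flat trend fallback for tiny matrices
        slope, intercept = 0.0, float(np.log(np.median(raw)))
    with np.errstate(divide="ignore"):
        trend = np.exp(intercept + slope * np.log(np.maximum(mean, 1e-12)))
    trend = np.clip(trend, min_disp, max_disp)
    final = np.exp((1 - shrinkage) * np.log(raw) + shrinkage * np.log(trend))
    final = np.clip(final, min_disp, max_disp)
    return DispersionFit(
        raw=pd.Series(raw, index=genes), trend=pd.Series(trend, index=genes),
        final=pd.Series(final, index=genes),
        trend_coef=(float(intercept), float(slope)))


def _nb_deviance(y, mu, alpha):
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        r = 1.0 / alpha
        term2 = (y + r) * np.log((1 + alpha * y) / (1 + alpha * mu))
    return 2.0 * (term1 - term2).sum(axis=1)


@dataclass
class NbWaldFit:
    """Full fit: per-gene results table plus the dispersion fit."""

    results: pd.DataFrame
    dispersion: DispersionFit
    size_factors: pd.Series
    design_columns: list[str]
    n_nonconverged: int = 0


def fit_nb_wald(counts: ExpressionMatrix, design: pd.DataFrame,
                group_col: str = "kras_wildtype",
                shrinkage: float = 0.5,
                prefilter: bool = True) -> NbWaldFit:
    """Fit the NB Wald model gene-by-gene (vectorized IRLS).

    ``design`` is samples x covariates (no intercept column; one is added),
    indexed like the count matrix columns, containing the group indicator
    named ``group_col`` (mutant = 0, wildtype = 1) and any batch dummies.
    Genes whose IRLS does not converge are flagged and excluded from the
    BH family.
    """
    if counts.scale != "raw_counts":
        raise ValueError("DEA requires raw counts")
    if group_col not in design.columns:
        raise ValueError(f"design lacks group column {group_col!r}")
    design = design.loc[counts.sample_ids]
    X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    colnames = ["intercept", *design.columns]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full rank")
    gi = colnames.index(group_col)
    for col in design.columns:
        if col == group_col and design[col].nunique() < 2:
            raise ValueError("both groups must be present")
    grp = design[group_col].to_numpy()
    if min((grp == 0).sum(), (grp == 1).sum()) < 2:
        raise ValueError("each group needs >= 2 samples")

    genes = prefilter_genes(counts) if prefilter else counts.gene_ids
    Y = counts.values.loc[genes].to_numpy(dtype=float)
    s = size_factors(counts).to_numpy()
    offset = np.log(s)[None, :]
    norm = Y / s[None, :]
    disp = estimate_dispersions(norm, genes, shrinkage=shrinkage)
    alpha = disp.final.to_numpy()[:, None]

    G, n = Y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    beta[:, 0] = np.log(np.maximum(norm.mean(axis=1), 1e-8))
    dev = np.full(G, np.inf)
    active = np.ones(G, dtype=bool)
    n_iter = 0
    while active.any() and n_iter < MAX_IRLS_ITER:
        n_iter += 1
        eta = np.clip(offset + beta @ X.T, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (Y - mu) / mu
        A = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True)
        A += np.eye(p)[None, :, :] * 1e-10
        b = np.einsum("np,gn->gp", X, W * z, optimize=True)
        idx = np.nonzero(active)[0]
        try:
            beta_new = np.linalg.solve(A[idx], b[idx][..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.array([np.linalg.lstsq(A[i], b[i], rcond=None)[0]
                                 for i in idx])
        beta[idx] = beta_new
        eta = np.clip(offset + beta @ X.T, -30.0, 30.0)
        new_dev = _nb_deviance(Y, np.exp(eta), alpha)
        rel = np.abs(new_dev - dev) / (np.abs(new_dev) + 0.1)
        active = active & (rel > DEVIANCE_RTOL)
        dev = new_dev
    converged = ~active

    eta = np.clip(offset + beta @ X.T, -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha * mu)
    A = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True)
    A += np.eye(p)[None, :, :] * 1e-10
    cov = np.linalg.inv(A)
    se_nat = np.sqrt(np.maximum(cov[:, gi, gi], 1e-300))
    l2fc = beta[:, gi] / LOG2
    se = se_nat / LOG2
    wald = beta[:, gi] / se_nat
    p_raw = 2.0 * special.ndtr(-np.abs(wald))

    res = pd.DataFrame({
        "gene": genes,
        "mean_expression": norm.mean(axis=1),
        "l2fc": l2fc, "se": se, "wald_stat": wald,
        "p_raw": p_raw, "converged": converged,
    }).set_index("gene")
    # batch coefficients, reported for confound diagnostics
    for j, name in enumerate(colnames):
        if j not in (0, gi):
            res[f"beta_{name}_l2"] = beta[:, j] / LOG2
    res["p_adj"] = np.nan
    fam = res.index[res["converged"]]
    if len(fam):
        res.loc[fam, "p_adj"] = bh_adjust(res.loc[fam, "p_raw"].to_numpy())
    n_bad = int((~converged).sum())
    if n_bad:
        logger.warning("%d genes did not converge and were excluded from "
                       "the BH family", n_bad)
    return NbWaldFit(results=res, dispersion=disp,
                     size_factors=pd.Series(s, index=counts.sample_ids),
                     design_columns=colnames, n_nonconverged=n_bad)


@dataclass
class SignatureGenes:
    up: list[str]
    down: list[str]
    p_thresh: float
    l2fc_thresh: float
    lenient_up: int = 0     # tally at adjusted p < 0.05, any fold change sign
    lenient_down: int = 0

    def __post_init__(self):
        if set(self.up) & set(self.down):
            raise ValueError("up and down signature lists overlap")

    @property
    def genes(self) -> list[str]:
        return self.up + self.down


def select_signature(results: pd.DataFrame, p_thresh: float = 0.005,
                     l2fc_thresh: float = 2.5,
                     lenient_p: float = 0.05) -> SignatureGenes:
    """Conservative signature selection: adjusted p strictly below
    ``p_thresh`` AND |l2fc| strictly above ``l2fc_thresh``."""
    ok = results["p_adj"].notna()
    up = results.index[ok & (results["p_adj"] < p_thresh)
                       & (results["l2fc"] > l2fc_thresh)]
    down = results.index[ok & (results["p_adj"] < p_thresh)
                         & (results["l2fc"] < -l2fc_thresh)]
    len_up = int((ok & (results["p_adj"] < lenient_p) & (results["l2fc"] > 0)).sum())
    len_down = int((ok & (results["p_adj"] < lenient_p) & (results["l2fc"] < 0)).sum())
    return SignatureGenes(up=list(up), down=list(down), p_thresh=p_thresh,
                          l2fc_thresh=l2fc_thresh,
                          lenient_up=len_up, lenient_down=len_down)


def confounder_scan(signature_genes: list[str], expression: ExpressionMatrix,
                    clinical: pd.DataFrame,
                    covariates: list[str] = ("age_at_diagnosis", "ca19_9"),
                    flag_p: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of each signature gene with each clinical
    covariate, BH-adjusted within each covariate family."""
    shared = [s for s in expression.sample_ids if s in clinical.index]
    rows = []
    for cov in covariates:
        vals = clinical.loc[shared, cov].astype(float)
        use = vals.notna()
        if vals[use].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
        ids = [s for s, u in zip(shared, use) if u]
        pvals, rhos = [], []
        present = [g for g in signature_genes if g in expression.values.index]
        for gene in present:
            rho, p = spearman(expression.values.loc[gene, ids].to_numpy(),
                              vals[use].to_numpy())
            rhos.append(rho)
            pvals.append(p)
        padj = bh_adjust(pvals) if pvals else []
        for gene, rho, p, pa in zip(present, rhos, pvals, padj):
            rows.append({"gene": gene, "covariate": cov, "rho": rho,
                         "p_raw": p, "p_adj": pa, "flagged": pa < flag_p})
    return pd.DataFrame(rows)


def l2fc_by_cnv_class(results: pd.DataFrame,
                      gene_classes: dict[str, list[str]],
                      background: str = "background",
                      value_col: str = "l2fc") -> pd.DataFrame:
    """Rank-sum comparison of fold-change distributions between each
    amplified gene class and the background class; class medians
    reported."""
    if background not in gene_classes:
        raise ValueError(f"gene_classes must include {background!r}")
    vals = {}
    for name, genes in gene_classes.items():
        present = [g for g in genes if g in results.index]
        if not present:
            raise ValueError(f"class {name!r} has no genes in results")
        vals[name] = results.loc[present, value_col].dropna().to_numpy()
    rows = []
    bg = vals[background]
    for name, v in vals.items():
        row = {"gene_class": name, "n_genes": len(v),
               "median_l2fc": float(np.median(v))}
        if name != background:
            row["p_vs_background"] = wilcoxon_ranksum(v, bg).p_value
        else:
            row["p_vs_background"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def crosscohort_concordance(signature: SignatureGenes,
                            validation_l2fc: pd.Series) -> pd.DataFrame:
    """One-sided signed-rank shift tests of validation fold changes in each
    signature direction (up genes tested for a positive shift, down genes
    for a negative shift)."""
    rows = []
    for direction, genes, alternative in (
            ("up", signature.up, "greater"), ("down", signature.down, "less")):
        present = [g for g in genes if g in validation_l2fc.index
                   and pd.notna(validation_l2fc[g])]
        missing = sorted(set(genes) - set(present))
        if len(present) < 3:
            raise ValueError(
                f"{direction}: need >= 3 signature genes in validation table")
        v = validation_l2fc[present].to_numpy(dtype=float)
        res = wilcoxon_signedrank(v, alternative=alternative)
        rows.append({"direction": direction, "n_genes": len(present),
                     "n_missing": len(missing),
                     "median_validation_l2fc": float(np.median(v)),
                     "p_one_sided": res.p_value})
    return pd.DataFrame(rows)
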