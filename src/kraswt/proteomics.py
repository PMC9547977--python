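"""Protein-level group comparison and mRNA-protein concordance.

The protein matrix is assumed already normalized log2 intensity (median
centering happens upstream in the quantification pipeline; an optional
switch re-centers here).  Group fold changes use an empirical-Bayes
moderated t in the limma style: per-gene variances are shrunk toward a
pooled prior whose degrees of freedom come from the spread of the
observed log-variances.  The peptide-count-dependent variance model of
dedicated proteomics DE tools is deliberately not replicated — peptide
counts are not part of the input contract — and results record that
simplification in their metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as _sstats

from .stats import bh_adjust, spearman

logger = logging.getLogger(__name__)

MODERATION_NOTE = "limma-style empirical-Bayes moderation (no peptide-count variance model)"


def median_center(proteins: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's median log2 intensity."""
    return proteins.sub(proteins.median(axis=0), axis=1)


def mrna_protein_rho(expression: pd.DataFrame, proteins: pd.DataFrame,
                     per_gene: bool = False) -> dict:
    """Across-gene Spearman correlation of mean mRNA vs mean protein.

    The default aggregates to per-gene means and correlates across the
    shared genes; ``per_gene=True`` instead correlates each gene across
    shared samples and reports the median per-gene rho.
    """
    shared = [g for g in expression.index if g in proteins.index]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes (need >= 10)")
    if per_gene:
        shared_samples = [s for s in expression.columns if s in proteins.columns]
        rhos = []
        for g in shared:
            e = expression.loc[g, shared_samples].astype(float)
            p = proteins.loc[g, shared_samples].astype(float)
            ok = e.notna() & p.notna()
            if ok.sum() >= 5:
                rhos.append(spearman(e[ok].to_numpy(), p[ok].to_numpy())[0])
        return {"rho": float(np.median(rhos)), "p": np.nan,
                "n_genes": len(rhos), "aggregation": "median per-gene rho"}
    e_mean = expression.loc[shared].mean(axis=1)
    p_mean = proteins.loc[shared].mean(axis=1)
    rho, p = spearman(e_mean.to_numpy(), p_mean.to_numpy())
    return {"rho": rho, "p": p, "n_genes": len(shared),
            "aggregation": "across genes on per-gene means"}


@dataclass
class ModeratedTestResult:
    table: pd.DataFrame
    prior_df: float
    prior_var: float
    note: str = MODERATION_NOTE


def _fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on sample variances
    (Smyth): returns (prior_df d0, prior_var s0^2)."""
    ok = s2 > 0
    z = np.log(s2[ok])
    dfo = df[ok].astype(float)
    e = z - special.digamma(dfo / 2.0) + np.log(dfo / 2.0)
    e_mean = e.mean()
    e_var = max(np.var(e, ddof=1) - np.mean(special.polygamma(1, dfo / 2.0)), 0.0)
    if e_var <= 1e-12:
        return np.inf, float(np.exp(e_mean))

    def objective(log_half_d0):
        return special.polygamma(1, np.exp(log_half_d0)) - e_var

    try:
        sol = optimize.brentq(objective, np.log(1e-4), np.log(1e6))
        d0 = 2.0 * np.exp(sol)
    except ValueError:
        d0 = np.inf
    if np.isfinite(d0):
        s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        s0 = float(np.exp(e_mean))
    return float(d0), s0


def protein_group_l2fc(proteins: pd.DataFrame, groups: dict[str, list[str]],
                       prior_df: float | None = None,
                       center: bool = False) -> ModeratedTestResult:
    """Per-gene group difference of mean log2 intensity with a moderated t.

    ``groups`` maps two group names to sample lists; the first group is
    the numerator (wildtype-like) of the fold change.  Genes quantified
    in fewer than 2 samples in either group are excluded with a log
    entry.  ``prior_df`` overrides the estimated prior degrees of
    freedom (0 -> ordinary t, inf -> pooled-variance z).
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    if center:
        proteins = median_center(proteins)
    (name_a, ids_a), (name_b, ids_b) = groups.items()
    ids_a = [s for s in ids_a if s in proteins.columns]
    ids_b = [s for s in ids_b if s in proteins.columns]
    a = proteins[ids_a].to_numpy(dtype=float)
    b = proteins[ids_b].to_numpy(dtype=float)
    na = (~np.isnan(a)).sum(axis=1)
    nb = (~np.isnan(b)).sum(axis=1)
    usable = (na >= 2) & (nb >= 2)
    n_drop = int((~usable).sum())
    if n_drop:
        logger.info("excluded %d genes quantified in < 2 samples per group",
                    n_drop)
    genes = proteins.index[usable]
    a, b = a[usable], b[usable]
    na, nb = na[usable], nb[usable]
    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    l2fc = mean_a - mean_b
    var_a = np.nanvar(a, axis=1, ddof=1)
    var_b = np.nanvar(b, axis=1, ddof=1)
    df_g = na + nb - 2
    s2 = ((na - 1) * var_a + (nb - 1) * var_b) / df_g
    if prior_df is None:
        d0, s0 = _fit_f_dist(s2, df_g)
    else:
        d0 = prior_df
        s0 = float(np.median(s2)) if np.isfinite(d0) and d0 > 0 else 0.0
    if d0 == 0:
        s2_mod = s2
        df_mod = df_g.astype(float)
    elif np.isinf(d0):
        s0_eff = s0 if prior_df is None else float(np.mean(s2))
        s2_mod = np.full_like(s2, s0_eff)
        df_mod = np.full_like(s2, np.inf)
    else:
        s2_mod = (d0 * s0 + df_g * s2) / (d0 + df_g)
        df_mod = df_g + d0
    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    se = np.maximum(se, 1e-12)
    t = l2fc / se
    p = np.where(np.isinf(df_mod),
                 2.0 * special.ndtr(-np.abs(t)),
                 2.0 * _sstats.t.sf(np.abs(t), df=np.where(
                     np.isinf(df_mod), 1.0, df_mod)))
    table = pd.DataFrame({
        "gene": genes,
        "protein_l2fc": l2fc, "moderated_t": t,
        "p_raw": np.minimum(p, 1.0),
        f"n_{name_a}": na, f"n_{name_b}": nb,
    }).set_index("gene")
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy()) if len(table) else []
    return ModeratedTestResult(table=table, prior_df=float(d0),
                               prior_var=float(s0))


def protein_l2fc_by_cnv_class(results: pd.DataFrame,
                              gene_classes: dict[str, list[str]],
                              background: str = "background") -> pd.DataFrame:
    """Identical contract to the mRNA fold-change-by-CNV-class comparison,
    applied to protein fold changes."""
    from .dea import l2fc_by_cnv_class
    return l2fc_by_cnv_class(results, gene_classes, background=background,
                             value_col="protein_l2fc")
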