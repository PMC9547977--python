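"""Transcriptional subtype assignment.

Moffitt basal-like vs classical calls come from a top-scoring-pairs (TSP)
classifier: per gene pair an indicator of whether the basal-associated
gene out-ranks its partner within the sample, combined through a logistic
model into a basal-like probability.  Probability cutoffs stratify
samples into basal-like (> 0.75), classical (< 0.25) and intermediate
([0.25, 0.75]).  Published classifier pairs and weights are data, not an
algorithm of this package: they load from an editable TSV (a synthetic
default ships for tests).

Metabolic subtypes use a quadrant rule on median z-scored expression of
glycolytic versus cholesterogenic gene modules.  Collisson/Bailey-style
scheme assignment runs consensus clustering on scheme genes at a fixed k
and labels each cluster by its dominant module score — a deterministic
stand-in for the manual dendrogram cut of the semi-automatic procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .consensus import ConsensusParams, consensus_matrices, final_labels
from .core_io import ExpressionMatrix, zscore_rows
from .stats import wilcoxon_ranksum

MOFFITT_BASAL_CUT = 0.75
MOFFITT_CLASSICAL_CUT = 0.25


@dataclass
class TspClassifierParams:
    pairs: list[tuple[str, str]]  # (gene_high_basal, gene_low_basal)
    weights: list[float]
    intercept: float

    def __post_init__(self):
        if len(self.pairs) != len(self.weights):
            raise ValueError("one weight per pair required")
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"pair genes must differ: {a}")


def read_tsp_params(path) -> TspClassifierParams:
    """Read classifier pairs/weights from TSV; a trailing ``#intercept``
    line carries the logistic intercept (default 0)."""
    pairs, weights, intercept = [], [], 0.0
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_high_basal"):
            raise ValueError(f"{path}: unexpected header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#intercept"):
                intercept = float(line.split("\t")[1])
                continue
            a, b, w = line.split("\t")[:3]
            pairs.append((a, b))
            weights.append(float(w))
    return TspClassifierParams(pairs=pairs, weights=weights, intercept=intercept)


def default_tsp_params() -> TspClassifierParams:
    """Synthetic default classifier matched to the simulated cohort's
    basal/classical modules."""
    ref = resources.files("kraswt.data") / "purist_pairs_synthetic.tsv"
    with resources.as_file(ref) as path:
        return read_tsp_params(path)


def load_gene_list(name: str) -> list[str]:
    ref = resources.files("kraswt.data") / name
    return [l.strip() for l in ref.read_text().splitlines() if l.strip()]


def tsp_score(sample_expression: pd.Series,
              params: TspClassifierParams) -> float:
    """Basal-like probability of one sample.

    Depends on expression only through within-sample ranks of the pair
    genes, hence invariant to monotone transforms.  A tie counts as
    indicator 0 (conservative toward classical).  Pairs with either gene
    unmeasured are dropped with a warning.
    """
    total = params.intercept
    evaluable = 0
    for (hi, lo), w in zip(params.pairs, params.weights):
        if hi not in sample_expression.index or lo not in sample_expression.index \
                or pd.isna(sample_expression[hi]) or pd.isna(sample_expression[lo]):
            continue
        evaluable += 1
        if sample_expression[hi] > sample_expression[lo]:
            total += w
    if evaluable == 0:
        raise ValueError("no evaluable classifier pair in sample")
    if evaluable < len(params.pairs):
        warnings.warn(f"{len(params.pairs) - evaluable} classifier pairs "
                      "dropped (unmeasured genes)", stacklevel=2)
    return float(1.0 / (1.0 + np.exp(-total)))


def assign_moffitt(score: float) -> str:
    """Strict cutoffs: basal-like > 0.75, classical < 0.25, otherwise
    intermediate (both boundaries fall to intermediate)."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score {score} outside [0, 1]")
    if score > MOFFITT_BASAL_CUT:
        return "basal-like"
    if score < MOFFITT_CLASSICAL_CUT:
        return "classical"
    return "intermediate"


def moffitt_calls(expression: ExpressionMatrix,
                  params: TspClassifierParams | None = None) -> pd.DataFrame:
    """Per-sample TSP score and Moffitt call."""
    if params is None:
        params = default_tsp_params()
    rows = []
    for sid in expression.sample_ids:
        score = tsp_score(expression.values[sid], params)
        rows.append({"sample_id": sid, "scheme": "moffitt",
                     "score": score, "call": assign_moffitt(score)})
    return pd.DataFrame(rows)


def module_median(expression: ExpressionMatrix,
                  gene_list: list[str]) -> pd.Series:
    """Per-sample median expression over the measured listed genes."""
    present = [g for g in gene_list if g in expression.values.index]
    if not present:
        raise ValueError("no listed gene present in the expression matrix")
    return expression.values.loc[present].median(axis=0)


def compare_module_median(expression: ExpressionMatrix, gene_list: list[str],
                          group_a: list[str], group_b: list[str]) -> dict:
    """Rank-sum contrast of per-sample module medians between two sample
    groups (e.g. wildtype-classical vs mutant-classical)."""
    med = module_median(expression, gene_list)
    res = wilcoxon_ranksum(med[group_a].to_numpy(), med[group_b].to_numpy())
    return {"median_a": float(med[group_a].median()),
            "median_b": float(med[group_b].median()),
            "p_value": res.p_value, "n_a": len(group_a), "n_b": len(group_b)}


def assign_metabolic(expression: ExpressionMatrix,
                     glycolytic_genes: list[str] | None = None,
                     cholesterogenic_genes: list[str] | None = None
                     ) -> pd.DataFrame:
    """Quadrant rule on per-sample median z-scored module expression.

    With both module scores strictly above their cohort medians the call
    is mixed; both at or below, quiescent (the degenerate all-identical
    cohort therefore collapses to quiescent).
    """
    if glycolytic_genes is None:
        glycolytic_genes = load_gene_list("glycolytic_genes.txt")
    if cholesterogenic_genes is None:
        cholesterogenic_genes = load_gene_list("cholesterogenic_genes.txt")
    z = expression if expression.scale == "zscore" else zscore_rows(expression)
    gly = module_median(z, glycolytic_genes)
    chol = module_median(z, cholesterogenic_genes)
    gly_hi = gly > gly.median()
    chol_hi = chol > chol.median()
    rows = []
    for sid in z.sample_ids:
        if gly_hi[sid] and not chol_hi[sid]:
            call = "glycolytic"
        elif chol_hi[sid] and not gly_hi[sid]:
            call = "cholesterogenic"
        elif gly_hi[sid] and chol_hi[sid]:
            call = "mixed"
        else:
            call = "quiescent"
        rows.append({"sample_id": sid, "scheme": "metabolic", "call": call,
                     "glycolytic_score": float(gly[sid]),
                     "cholesterogenic_score": float(chol[sid])})
    return pd.DataFrame(rows)


def consensus_subtype(expression: ExpressionMatrix,
                      scheme_gene_lists: dict[str, list[str]],
                      k: int, scheme: str = "collisson",
                      params: ConsensusParams | None = None) -> pd.DataFrame:
    """Consensus clustering on z-scored scheme genes at fixed k, each
    cluster labeled by its highest mean module score (ties -> ambiguous).
    """
    all_genes = sorted({g for genes in scheme_gene_lists.values() for g in genes})
    present = [g for g in all_genes if g in expression.values.index]
    if not present:
        raise ValueError("no scheme genes present in the expression matrix")
    z = expression if expression.scale == "zscore" else zscore_rows(expression)
    data = z.values.loc[present]
    if params is None:
        params = ConsensusParams(k_range=tuple(range(2, max(k, 2) + 1)))
    if k == 1:
        labels = pd.Series(1, index=z.sample_ids, name="cluster")
    else:
        result = consensus_matrices(data, params)
        labels = final_labels(result, k=k)
    module_scores = {name: module_median(
        ExpressionMatrix(values=z.values.loc[
            [g for g in genes if g in z.values.index]], scale="zscore"),
        [g for g in genes if g in z.values.index])
        for name, genes in scheme_gene_lists.items()
        if any(g in z.values.index for g in genes)}
    calls = {}
    for cluster in sorted(labels.unique()):
        ids = labels.index[labels == cluster]
        means = {name: float(s[ids].mean()) for name, s in module_scores.items()}
        best = max(means.values())
        winners = [name for name, v in means.items() if v == best]
        calls[cluster] = winners[0] if len(winners) == 1 else "ambiguous"
    return pd.DataFrame({
        "sample_id": labels.index, "scheme": scheme,
        "cluster": labels.to_numpy(),
        "call": [calls[c] for c in labels.to_numpy()],
    })
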