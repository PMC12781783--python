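"""Biological analyses on a completed response matrix.

Sensitivity screening of previously missing entries, mutant vs wild-type
stratification of response distributions, four-group co-mutation analysis,
drug-gene association networks (significant in both observed and predicted
data), per-drug gene ranking, and tissue-level mean responses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import (ExpressionMatrix, MutationProfile, Orientation,
                   ResponseMatrix, TissueMap)
from .evaluation import pcc
from .pca import ExpressionPCA, back_project
from .solver import CompletionResult

logger = logging.getLogger(__name__)


@dataclass
class StratifiedComparison:
    """Rank-sum comparison of response distributions between strata."""

    drug_id: str
    gene_id: str
    group_sizes: dict[str, int]
    statistic: float
    p_value: float
    fold_change: float
    source: Literal["observed", "predicted"]
    underpowered: bool = False
    test: str = "wilcoxon_ranksum"


@dataclass
class DrugGeneNetwork:
    """Edges significant in BOTH the observed and the predicted data."""

    edges: pd.DataFrame  # drug, gene, p_observed, p_predicted, q_*
    alpha: float
    all_pairs: pd.DataFrame = None

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for _, row in self.edges.iterrows():
            g.add_node(row["drug"], kind="drug")
            g.add_node(row["gene"], kind="gene")
            g.add_edge(row["drug"], row["gene"],
                       p_observed=float(row["p_observed"]),
                       p_predicted=float(row["p_predicted"]))
        return g


@dataclass
class SensitivityCalls:
    """Previously missing entries predicted to cross the sensitivity threshold."""

    quantile: float
    thresholds: dict[str, float]
    calls: pd.DataFrame  # drug, cell_line, predicted_value, threshold
    excluded_drugs: list[str] = field(default_factory=list)


def screen_sensitive(observed: ResponseMatrix, predicted: np.ndarray,
                     quantile: float = 0.30,
                     orientation: Optional[Orientation] = None) -> SensitivityCalls:
    """Flag missing entries whose prediction falls in the most-sensitive
    `quantile` fraction of each drug's observed values.

    The threshold is the upper (1-q) observed quantile when higher values
    mean sensitivity, and the lower q quantile otherwise; quantiles use
    linear interpolation. Drugs with fewer than 4 observed entries are
    excluded with a warning.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    orientation = orientation or observed.orientation
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted matrix not aligned with observed")

    thresholds: dict[str, float] = {}
    rows = []
    excluded = []
    for j, drug in enumerate(observed.col_ids):
        obs = observed.observed_values(j)
        if obs.size < 4:
            excluded.append(drug)
            warnings.warn(f"drug {drug!r} has <4 observed entries; excluded "
                          "from sensitivity screening", stacklevel=2)
            continue
        if orientation == "higher_is_sensitive":
            thr = float(np.quantile(obs, 1.0 - quantile))
            hits = predicted[:, j] > thr
        else:
            thr = float(np.quantile(obs, quantile))
            hits = predicted[:, j] < thr
        thresholds[drug] = thr
        for i in np.flatnonzero(hits & ~observed.mask[:, j]):
            rows.append((drug, observed.row_ids[i],
                         float(predicted[i, j]), thr))
    calls = pd.DataFrame(rows, columns=["drug", "cell_line",
                                        "predicted_value", "threshold"])
    return SensitivityCalls(quantile, thresholds, calls, excluded)


def _sensitivity_transform(values: np.ndarray, orientation: Orientation,
                           reference_max: Optional[float] = None) -> np.ndarray:
    """Map responses so that larger always means more sensitive.

    When lower values mean sensitivity, uses (max - value) so group-mean
    ratios remain positive and interpretable.
    """
    if orientation == "higher_is_sensitive":
        return values
    ref = float(np.max(values)) if reference_max is None else reference_max
    return ref - values


def _ranksum(x: np.ndarray, y: np.ndarray, test: str) -> tuple[float, float]:
    if test == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    # exact null for small tie-free samples, normal approximation (with tie
    # correction) otherwise
    combined = np.concatenate([x, y])
    exact = (x.size + y.size) <= 25 and np.unique(combined).size == combined.size
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def stratify_by_mutation(responses: np.ndarray, mask: np.ndarray,
                         mutation: np.ndarray,
                         orientation: Orientation = "higher_is_sensitive",
                         drug_id: str = "", gene_id: str = "",
                         source: str = "observed",
                         test: str = "wilcoxon_ranksum") -> StratifiedComparison:
    """Two-sided rank-sum comparison of mutant vs wild-type responses.

    fold_change is the ratio of group mean sensitivities, with responses
    orientation-adjusted so larger means more sensitive. Groups with fewer
    than 3 usable responses flag the comparison underpowered (p left NaN).
    """
    responses = np.asarray(responses, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    mutation = np.asarray(mutation)
    mut = responses[mask & (mutation == 1)]
    wt = responses[mask & (mutation == 0)]
    if mut.size == 0 or wt.size == 0:
        raise ValueError("degenerate stratification: all cell lines are in "
                         "one mutation class")
    sizes = {"mutant": int(mut.size), "wild_type": int(wt.size)}

    all_vals = np.concatenate([mut, wt])
    ref = float(np.max(all_vals))
    sens_mut = _sensitivity_transform(mut, orientation, ref)
    sens_wt = _sensitivity_transform(wt, orientation, ref)
    wt_mean = sens_wt.mean()
    fold = float(sens_mut.mean() / wt_mean) if wt_mean != 0 else float("nan")

    if mut.size < 3 or wt.size < 3:
        return StratifiedComparison(drug_id, gene_id, sizes, float("nan"),
                                    float("nan"), fold, source,
                                    underpowered=True, test=test)
    statistic, p = _ranksum(mut, wt, test)
    return StratifiedComparison(drug_id, gene_id, sizes, statistic, p, fold,
                                source, test=test)


CO_MUTATION_CLASSES = ("WT/WT", "MUT/WT", "WT/MUT", "MUT/MUT")


def co_mutation_analysis(responses: np.ndarray, mask: np.ndarray,
                         mut_gene_a: np.ndarray, mut_gene_b: np.ndarray,
                         orientation: Orientation = "higher_is_sensitive",
                         drug_id: str = "", gene_a: str = "geneA",
                         gene_b: str = "geneB",
                         test: str = "wilcoxon_ranksum") -> dict:
    """Four-group stratification by the joint mutation status of two genes.

    Each mutated class is rank-sum tested against the double wild-type
    class, with fold changes relative to WT/WT; classes with fewer than 3
    usable members are counted but excluded from testing.
    """
    responses = np.asarray(responses, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    a = np.asarray(mut_gene_a)
    b = np.asarray(mut_gene_b)
    groups = {
        "WT/WT": mask & (a == 0) & (b == 0),
        "MUT/WT": mask & (a == 1) & (b == 0),
        "WT/MUT": mask & (a == 0) & (b == 1),
        "MUT/MUT": mask & (a == 1) & (b == 1),
    }
    sizes = {k: int(v.sum()) for k, v in groups.items()}
    values = {k: responses[v] for k, v in groups.items()}
    ref = float(np.max(responses[mask])) if mask.any() else 0.0

    summaries = {k: {"n": sizes[k],
                     "mean": float(v.mean()) if v.size else float("nan"),
                     "median": float(np.median(v)) if v.size else float("nan")}
                 for k, v in values.items()}

    wt = values["WT/WT"]
    sens_wt = _sensitivity_transform(wt, orientation, ref) if wt.size else wt
    comparisons: dict[str, StratifiedComparison] = {}
    for cls in ("MUT/WT", "WT/MUT", "MUT/MUT"):
        grp = values[cls]
        if grp.size == 0:
            continue
        sens_grp = _sensitivity_transform(grp, orientation, ref)
        fold = (float(sens_grp.mean() / sens_wt.mean())
                if wt.size and sens_wt.mean() != 0 else float("nan"))
        if grp.size < 3 or wt.size < 3:
            comparisons[cls] = StratifiedComparison(
                drug_id, f"{gene_a}/{gene_b}:{cls}",
                {"class": sizes[cls], "WT/WT": sizes["WT/WT"]},
                float("nan"), float("nan"), fold, "observed",
                underpowered=True, test=test)
            continue
        statistic, p = _ranksum(grp, wt, test)
        comparisons[cls] = StratifiedComparison(
            drug_id, f"{gene_a}/{gene_b}:{cls}",
            {"class": sizes[cls], "WT/WT": sizes["WT/WT"]},
            statistic, p, fold, "observed", test=test)
    return {"drug": drug_id, "genes": (gene_a, gene_b),
            "class_sizes": sizes, "summaries": summaries,
            "comparisons": comparisons}


def build_drug_gene_network(observed: ResponseMatrix, predicted: np.ndarray,
                            mutations: MutationProfile, alpha: float = 0.05,
                            genes: Optional[Sequence[str]] = None,
                            test: str = "wilcoxon_ranksum") -> DrugGeneNetwork:
    """Drug-gene association network from mutation stratification.

    For every (drug, gene) pair the mutant vs wild-type rank-sum test is run
    on the observed responses and on the predicted (completed) responses;
    an edge is emitted iff both raw p-values fall below alpha.
    Benjamini-Hochberg adjusted columns are attached for reference but do
    not gate edge inclusion.
    """
    predicted = np.asarray(predicted, dtype=float)
    gene_idx = range(len(mutations.gene_ids)) if genes is None else [
        mutations.gene_ids.index(g) for g in genes]
    full_mask = np.ones(observed.shape[0], dtype=bool)

    rows = []
    for j, drug in enumerate(observed.col_ids):
        for g in gene_idx:
            gene = mutations.gene_ids[g]
            calls = mutations.calls[:, g]
            if calls.min() == calls.max():
                continue
            try:
                obs_cmp = stratify_by_mutation(
                    observed.values[:, j], observed.mask[:, j], calls,
                    observed.orientation, drug, gene, "observed", test)
                pred_cmp = stratify_by_mutation(
                    predicted[:, j], full_mask, calls,
                    observed.orientation, drug, gene, "predicted", test)
            except ValueError:
                continue
            rows.append((drug, gene, obs_cmp.p_value, pred_cmp.p_value,
                         obs_cmp.fold_change, pred_cmp.fold_change))

    pairs = pd.DataFrame(rows, columns=["drug", "gene", "p_observed",
                                        "p_predicted", "fc_observed",
                                        "fc_predicted"])
    for col in ("p_observed", "p_predicted"):
        q = np.full(len(pairs), np.nan)
        ok = pairs[col].notna().to_numpy()
        if ok.any():
            q[ok] = multipletests(pairs.loc[ok, col], method="fdr_bh")[1]
        pairs["q" + col[1:]] = q
    keep = (pairs["p_observed"] < alpha) & (pairs["p_predicted"] < alpha)
    return DrugGeneNetwork(pairs[keep].reset_index(drop=True), alpha, pairs)


def rank_genes_per_drug(pca: Optional[ExpressionPCA],
                        result: CompletionResult,
                        expression: ExpressionMatrix,
                        drug_ids: Sequence[str],
                        method: Literal["model_weights", "correlation"] = "model_weights",
                        top_n: int = 1000) -> dict[str, pd.DataFrame]:
    """Rank genes per drug by model weight or expression correlation.

    ``model_weights`` scores gene g for drug j as the absolute gene-space
    weight |W Lambda|[g, j] of the fitted linear model; ``correlation``
    scores it as |PCC(expression[:, g], M_hat[:, j])|. Ties break
    lexicographically by gene id.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    gene_ids = np.asarray(expression.gene_ids)
    n = gene_ids.size

    if method == "model_weights" and (pca is None or result.Lambda is None):
        warnings.warn("model weights unavailable (no_pca variant); falling "
                      "back to correlation ranking", stacklevel=2)
        method = "correlation"

    if method == "model_weights":
        scores = np.abs(back_project(pca, result.Lambda))
    elif method == "correlation":
        scores = np.empty((n, len(drug_ids)))
        for j in range(len(drug_ids)):
            for g in range(n):
                scores[g, j] = abs(pcc(expression.values[:, g],
                                       result.M_hat[:, j]))
        scores = np.nan_to_num(scores, nan=0.0)
    else:
        raise ValueError(f"unknown ranking method {method!r}")

    out: dict[str, pd.DataFrame] = {}
    take = min(top_n, n)
    lex = np.argsort(gene_ids, kind="stable")
    for j, drug in enumerate(drug_ids):
        # stable sort on descending score over lexicographically ordered genes
        order = lex[np.argsort(-scores[lex, j], kind="stable")][:take]
        degenerate = bool(np.all(scores[:, j] == 0))
        df = pd.DataFrame({
            "rank": np.arange(1, take + 1),
            "gene": gene_ids[order],
            "score": scores[order, j],
            "method": method,
        })
        df.attrs["degenerate"] = degenerate
        out[drug] = df
    return out


def tissue_mean_response(predicted: np.ndarray, row_ids: Sequence[str],
                         drug_ids: Sequence[str],
                         tissues: TissueMap) -> pd.DataFrame:
    """Mean predicted response per (tissue, drug), with cell-line counts."""
    predicted = np.asarray(predicted, dtype=float)
    labels = [tissues.assignments.get(r) for r in row_ids]
    keep = [i for i, t in enumerate(labels) if t is not None]
    if not keep:
        raise ValueError("no mapped cell lines")
    df = pd.DataFrame(predicted[keep], columns=list(drug_ids))
    df["tissue"] = [labels[i] for i in keep]
    means = df.groupby("tissue").mean()
    means["n_cell_lines"] = df.groupby("tissue").size()
    return means
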