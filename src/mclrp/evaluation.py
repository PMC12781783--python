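"""Repeated 10-fold cross-validation with per-drug Pearson and Spearman scores.

Fold units are observed entries (cell line, drug pairs), stratified per
drug column so every drug contributes near-equally to every fold. Per-drug
correlations are computed on the predictions pooled across the folds of one
repeat, then averaged across repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import ResponseMatrix, denormalize, normalize_response
from .pca import ExpressionPCA, fit_pca
from .solver import SolverConfig, admm_solve

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    repeat_index: int
    fold_index: int
    test_entries: list[tuple[int, int]]
    seed: int


@dataclass
class CVReport:
    """Per-drug correlation summary plus the pooled held-out predictions."""

    drug_ids: list[str]
    pcc_per_repeat: np.ndarray  # (n_repeats, p); NaN = undefined
    scc_per_repeat: np.ndarray
    pooled_predictions: pd.DataFrame  # repeat, row, col, observed, predicted
    config: dict
    failed_folds: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def per_drug(self) -> pd.DataFrame:
        import warnings

        with warnings.catch_warnings():
            # a single repeat has no spread; sd columns are NaN by design
            warnings.simplefilter("ignore", RuntimeWarning)
            return self._per_drug()

    def _per_drug(self) -> pd.DataFrame:
        return pd.DataFrame({
            "drug": self.drug_ids,
            "mean_pcc": np.nanmean(self.pcc_per_repeat, axis=0),
            "sd_pcc": np.nanstd(self.pcc_per_repeat, axis=0, ddof=1),
            "mean_scc": np.nanmean(self.scc_per_repeat, axis=0),
            "sd_scc": np.nanstd(self.scc_per_repeat, axis=0, ddof=1),
            "n_undefined_pcc": np.isnan(self.pcc_per_repeat).sum(axis=0),
        })

    @property
    def mean_pcc(self) -> float:
        return float(np.nanmean(self.pcc_per_repeat))

    @property
    def mean_scc(self) -> float:
        return float(np.nanmean(self.scc_per_repeat))


def pcc(observed, predicted) -> float:
    """Pearson correlation; NaN when either vector is constant."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 paired values")
    xd = x - x.mean()
    yd = y - y.mean()
    den = np.sqrt((xd**2).sum() * (yd**2).sum())
    if den == 0:
        return float("nan")
    return float((xd * yd).sum() / den)


def scc(observed, predicted) -> float:
    """Spearman correlation as the Pearson correlation of average ranks.

    Equals 1 - 6*sum(d_i^2)/(k(k^2-1)) exactly when both vectors are
    tie-free; NaN when either vector is constant.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 paired values")
    return pcc(rankdata(x), rankdata(y))


def make_folds(rm: ResponseMatrix, n_folds: int = 10, n_repeats: int = 10,
               seed: int = 0) -> list[FoldPlan]:
    """Deal the observed entries of each drug column round-robin into folds.

    A single fold pointer advances across columns, so global fold sizes
    differ by at most one while each drug's entries are spread evenly.
    Deterministic given the seed.
    """
    m, p = rm.shape
    counts = rm.mask.sum(axis=0)
    for j, c in enumerate(counts):
        if c < 4:
            raise ValueError(
                f"drug {rm.col_ids[j]!r} has only {int(c)} observed entries "
                "(need >= 4 for cross-validation)")
    plans: list[FoldPlan] = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        folds: list[list[tuple[int, int]]] = [[] for _ in range(n_folds)]
        pointer = int(rng.integers(n_folds))
        col_order = rng.permutation(p)
        for j in col_order:
            rows = np.flatnonzero(rm.mask[:, j])
            rng.shuffle(rows)
            for i in rows:
                folds[pointer % n_folds].append((int(i), int(j)))
                pointer += 1
        for f, entries in enumerate(folds):
            plans.append(FoldPlan(rep, f, entries, seed))
    return plans


def cross_validate(rm: ResponseMatrix, expression, cfg: SolverConfig,
                   n_folds: int = 10, n_repeats: int = 10, seed: int = 0,
                   n_components: Optional[int] = None,
                   variance_target: Optional[float] = None,
                   pca: Optional[ExpressionPCA] = None) -> CVReport:
    """Entry-wise repeated k-fold CV of the completion model.

    For each fold the test entries are hidden from the RAW response matrix,
    the training data are re-normalized (no leakage of test entries into
    column statistics), the solver is run, and predictions are collected at
    the hidden positions on the de-normalized scale. Expression is never
    masked, so its PCA is fit once and shared across folds.
    """
    if rm.is_normalized:
        raise ValueError("cross_validate expects the raw response matrix")
    if pca is None and cfg.variant != "no_pca":
        pca = fit_pca(expression, n_components=n_components,
                      variance_target=variance_target)

    m, p = rm.shape
    plans = make_folds(rm, n_folds, n_repeats, seed)
    pcc_rep = np.full((n_repeats, p), np.nan)
    scc_rep = np.full((n_repeats, p), np.nan)
    records = []
    failed: list[tuple[int, int, str]] = []

    for rep in range(n_repeats):
        pred = np.full((m, p), np.nan)
        for plan in (pl for pl in plans if pl.repeat_index == rep):
            train = rm.copy()
            idx = tuple(np.array(plan.test_entries).T)
            train.mask[idx] = False
            train.values[idx] = np.nan
            try:
                train_norm = normalize_response(train)
                result = admm_solve(train_norm, pca, cfg)
            except (RuntimeError, ValueError) as exc:
                failed.append((rep, plan.fold_index, str(exc)))
                logger.warning("fold (%d, %d) failed: %s", rep,
                               plan.fold_index, exc)
                continue
            raw_pred = denormalize(train_norm, result.M_hat)
            pred[idx] = raw_pred[idx]

        for j in range(p):
            held = rm.mask[:, j] & ~np.isnan(pred[:, j])
            if held.sum() >= 2:
                pcc_rep[rep, j] = pcc(rm.values[held, j], pred[held, j])
                scc_rep[rep, j] = scc(rm.values[held, j], pred[held, j])
            rows = np.flatnonzero(held)
            records.extend(
                (rep, rm.row_ids[i], rm.col_ids[j], rm.values[i, j],
                 pred[i, j]) for i in rows)

    pooled = pd.DataFrame(records, columns=["repeat", "cell_line", "drug",
                                            "observed", "predicted"])
    return CVReport(list(rm.col_ids), pcc_rep, scc_rep, pooled,
                    config={"solver": vars(cfg),
                            "n_folds": n_folds, "n_repeats": n_repeats,
                            "seed": seed},
                    failed_folds=failed)
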