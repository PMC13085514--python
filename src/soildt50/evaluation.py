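"""Model evaluation: nested cross-validation, accuracy metrics, and the
three uncertainty-calibration diagnostics (ECE, ENCE, distance-based
calibration).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, pearsonr, spearmanr
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold

from .features import (
    FeatureMatrix,
    FeatureSetSpec,
    featurize,
    fit_scale,
    apply_scale,
    select_features,
    subset_columns,
    tanimoto_knn_distance,
)
from .prob_models import (
    KernelSpec,
    PredictiveDistribution,
    TrainingSet,
    fit_gpr,
    predict_gpr,
)

logger = logging.getLogger(__name__)

#: default nominal central-coverage grid for the ECE: 0.05, 0.10, ..., 0.95
DEFAULT_COVERAGE_LEVELS = tuple(np.round(np.arange(0.05, 0.951, 0.05), 10))


class DegenerateBinError(ValueError):
    """Raised when an ENCE bin has zero root-mean-variance."""


@dataclass(frozen=True)
class CVConfig:
    """Nested cross-validation configuration. Folds partition compounds."""

    outer_folds: int = 5
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class EvaluationReport:
    """Pooled outer-fold metrics plus the per-fold breakdown."""

    r2: float
    rmse: float
    ece: float
    ence: float
    dist_pearson: float
    dist_spearman: float
    per_fold: list[dict] = field(default_factory=list)
    chosen_candidates: list[dict] = field(default_factory=list)
    fold_assignment: dict = field(default_factory=dict)
    #: pooled outer-test predictions: compound_id, fold, pred_mean, pred_std, truth
    predictions: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "ece": self.ece,
            "ence": self.ence,
            "dist_pearson": self.dist_pearson,
            "dist_spearman": self.dist_spearman,
            "per_fold": self.per_fold,
            "chosen_candidates": self.chosen_candidates,
        }


def _means_stds(preds: Sequence[PredictiveDistribution]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([p.pred_mean for p in preds]),
        np.array([p.pred_std for p in preds]),
    )


def expected_calibration_error(
    preds: Sequence[PredictiveDistribution],
    truth: Sequence[float],
    coverage_levels: Sequence[float] = DEFAULT_COVERAGE_LEVELS,
) -> float:
    """Mean absolute gap between nominal and empirical central coverage.

    For each nominal level p the empirical coverage is the fraction of
    truths inside ``mean +/- z_{(1+p)/2} * sd``; the ECE averages
    ``|coverage - p|`` over the level grid.
    """
    truth = np.asarray(truth, dtype=float)
    if len(preds) != len(truth):
        raise ValueError(f"length mismatch: {len(preds)} preds vs {len(truth)} truths")
    if len(preds) < 20:
        warnings.warn("ECE on fewer than 20 points is unstable")
    mean, std = _means_stds(preds)
    z_abs = np.abs(truth - mean) / std
    gaps = []
    for p in coverage_levels:
        z_crit = norm.ppf((1.0 + p) / 2.0)
        coverage = float((z_abs <= z_crit).mean())
        gaps.append(abs(coverage - p))
    return float(np.mean(gaps))


def expected_normalized_calibration_error(
    preds: Sequence[PredictiveDistribution],
    truth: Sequence[float],
    n_bins: int = 10,
) -> float:
    """Binned check that residual magnitudes scale with predicted SDs.

    Points are sorted by pred_std into *n_bins* equal-count bins; per bin,
    RMV = sqrt(mean pred_std^2) and RMSE = sqrt(mean residual^2);
    ENCE = mean over bins of |RMV - RMSE| / RMV.
    """
    truth = np.asarray(truth, dtype=float)
    if len(preds) != len(truth):
        raise ValueError(f"length mismatch: {len(preds)} preds vs {len(truth)} truths")
    if len(preds) < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} points, got {len(preds)}")
    mean, std = _means_stds(preds)
    order = np.argsort(std, kind="stable")
    residual_sq = (truth - mean) ** 2
    bins = np.array_split(order, n_bins)
    terms = []
    for idx in bins:
        rmv = np.sqrt(np.mean(std[idx] ** 2))
        if rmv == 0:
            raise DegenerateBinError("ENCE bin with zero root-mean-variance")
        rmse = np.sqrt(np.mean(residual_sq[idx]))
        terms.append(abs(rmv - rmse) / rmv)
    return float(np.mean(terms))


def distance_calibration(
    preds: Sequence[PredictiveDistribution],
    query_smiles: Sequence[str],
    train_smiles: Sequence[str],
    k: int = 5,
) -> tuple[float, float]:
    """Correlation between Tanimoto k-NN distance to the training set and
    the predicted SD, as (Pearson r, Spearman rho).

    Degenerate inputs (constant distances or constant SDs) have no defined
    correlation and are returned as NaN — flagged, never silently 0.
    """
    if len(preds) < 3:
        raise ValueError("need at least 3 queries for a correlation")
    _, std = _means_stds(preds)
    dist = tanimoto_knn_distance(query_smiles, train_smiles, k=k)
    if np.ptp(dist) == 0 or np.ptp(std) == 0:
        warnings.warn("constant distances or SDs: correlation undefined (NaN)")
        return (float("nan"), float("nan"))
    r = pearsonr(dist, std).statistic
    rho = spearmanr(dist, std).statistic
    return (float(r), float(rho))


@dataclass(frozen=True)
class Candidate:
    """One (feature set, kernel spec) entry of the nested-CV search space."""

    feature_spec: FeatureSetSpec
    kernel_spec: KernelSpec
    label: str = ""


def _fit_candidate_pipeline(
    records, y, noise, cand: Candidate, seed: int
):
    """Featurize + scale + select + fit on a training partition only."""
    raw = featurize(records, cand.feature_spec)
    scaled = fit_scale(raw)
    selected, report = select_features(scaled)
    train = TrainingSet(X=selected, y=y, noise=noise)
    model = fit_gpr(train, cand.kernel_spec, seed=seed)
    state = {
        "scaler_state": scaled.scaler_state,
        "selected": selected.feature_names,
        "model": model,
        "feature_spec": cand.feature_spec,
    }
    return state


def _predict_pipeline(state, records):
    raw = featurize(records, state["feature_spec"])
    scaled = apply_scale(raw, state["scaler_state"])
    query = subset_columns(scaled, state["selected"])
    return predict_gpr(state["model"], query)


def nested_cv(
    records,
    y: np.ndarray,
    noise: np.ndarray,
    candidates: Sequence[Candidate],
    cv: CVConfig,
) -> EvaluationReport:
    """5x5 (by default) nested cross-validation over compounds.

    Per outer fold the inner CV picks the candidate with the lowest mean
    inner RMSE; the winner is refit on the full outer-train partition and
    scored on the outer-test partition. Scaling and feature selection are
    re-fit inside every training partition — no leakage. All headline
    metrics are computed on the pooled outer-test predictions; the
    per-fold breakdown is also reported.
    """
    records = list(records)
    y = np.asarray(y, dtype=float)
    noise = np.asarray(noise, dtype=float)
    n = len(records)
    # fold assignment is a deterministic function of (ids, seed)
    order = np.argsort([r.compound_id for r in records], kind="stable")
    outer = KFold(n_splits=cv.outer_folds, shuffle=True, random_state=cv.seed)

    pooled_preds: list[PredictiveDistribution] = []
    pooled_truth: list[float] = []
    pooled_smiles: list[str] = []
    per_fold, chosen = [], []
    prediction_rows: list[dict] = []
    fold_assignment: dict[str, int] = {}
    fold_distances: list[np.ndarray] = []

    for fold_no, (tr_pos, te_pos) in enumerate(outer.split(order)):
        tr_idx, te_idx = order[tr_pos], order[te_pos]
        for i in te_idx:
            fold_assignment[records[i].compound_id] = fold_no
        tr_records = [records[i] for i in tr_idx]
        te_records = [records[i] for i in te_idx]

        best_cand, best_rmse = None, np.inf
        if len(candidates) == 1:
            best_cand = candidates[0]
        else:
            inner = KFold(n_splits=cv.inner_folds, shuffle=True,
                          random_state=cv.seed + 1)
            for cand in candidates:
                rmses = []
                failed = False
                for itr, ite in inner.split(tr_idx):
                    try:
                        state = _fit_candidate_pipeline(
                            [tr_records[j] for j in itr],
                            y[tr_idx[itr]], noise[tr_idx[itr]],
                            cand, seed=cv.seed,
                        )
                        preds = _predict_pipeline(state, [tr_records[j] for j in ite])
                        mean = np.array([p.pred_mean for p in preds])
                        rmses.append(
                            float(np.sqrt(np.mean((mean - y[tr_idx[ite]]) ** 2)))
                        )
                    except Exception as exc:  # candidate failure is data, not a crash
                        logger.warning("candidate %s failed on inner fold: %s",
                                       cand.label or cand, exc)
                        failed = True
                        break
                if failed or not rmses:
                    continue
                mean_rmse = float(np.mean(rmses))
                if mean_rmse < best_rmse:
                    best_rmse, best_cand = mean_rmse, cand
        if best_cand is None:
            raise RuntimeError(f"every candidate failed on outer fold {fold_no}")

        state = _fit_candidate_pipeline(
            tr_records, y[tr_idx], noise[tr_idx], best_cand, seed=cv.seed
        )
        preds = _predict_pipeline(state, te_records)
        mean = np.array([p.pred_mean for p in preds])
        fold_r2 = float(r2_score(y[te_idx], mean))
        fold_rmse = float(np.sqrt(mean_squared_error(y[te_idx], mean)))
        per_fold.append(
            {"fold": fold_no, "r2": fold_r2, "rmse": fold_rmse,
             "n_test": len(te_idx), "candidate": best_cand.label}
        )
        chosen.append({"fold": fold_no, "candidate": best_cand.label,
                       "inner_rmse": None if len(candidates) == 1 else best_rmse})
        pooled_preds.extend(preds)
        pooled_truth.extend(y[te_idx].tolist())
        pooled_smiles.extend(r.smiles for r in te_records)
        prediction_rows.extend(
            {"compound_id": r.compound_id, "fold": fold_no,
             "pred_mean": p.pred_mean, "pred_std": p.pred_std, "truth": t}
            for r, p, t in zip(te_records, preds, y[te_idx])
        )
        # distance calibration: each test point against its own outer-train set
        train_smiles = [r.smiles for r in tr_records]
        fold_distances.append(
            tanimoto_knn_distance(
                [r.smiles for r in te_records], train_smiles,
                k=min(5, len(train_smiles)),
            )
        )

    truth = np.array(pooled_truth)
    mean = np.array([p.pred_mean for p in pooled_preds])
    dists = np.concatenate(fold_distances)
    stds = np.array([p.pred_std for p in pooled_preds])
    if np.ptp(dists) == 0 or np.ptp(stds) == 0:
        d_r, d_rho = float("nan"), float("nan")
    else:
        d_r = float(pearsonr(dists, stds).statistic)
        d_rho = float(spearmanr(dists, stds).statistic)

    return EvaluationReport(
        r2=float(r2_score(truth, mean)),
        rmse=float(np.sqrt(mean_squared_error(truth, mean))),
        ece=expected_calibration_error(pooled_preds, truth),
        ence=expected_normalized_calibration_error(
            pooled_preds, truth, n_bins=min(10, len(truth))
        ),
        dist_pearson=d_r,
        dist_spearman=d_rho,
        per_fold=per_fold,
        chosen_candidates=chosen,
        fold_assignment=fold_assignment,
        predictions=prediction_rows,
    )
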