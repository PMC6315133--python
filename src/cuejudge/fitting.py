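"""Parameter estimation, cross-validated model comparison and strategy labels.

Both models are scored by the root mean squared deviation (RMSD) between
their predictions and a participant's judgments.  CAM parameters minimize
squared error analytically (ordinary least squares); EBM similarities are
estimated by Nelder-Mead simplex search on an unconstrained logistic
reparameterization of the [0, 1] box, with seeded Latin-hypercube restarts.

Two fit regimes mirror the study's two test phases:

* leave-one-out cross-validation (``loocv_rmsd``) — parameters re-estimated
  with each test item held out, scored only on held-out predictions;
* projective fit (``projective_fit``) — parameters estimated on the final
  three training blocks, frozen, then scored on the test phase.

A participant (or synthetic agent) is labeled rule- or similarity-based by
whichever model attains the lower RMSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import qmc

from .models import (
    CAMParams,
    EBMParams,
    ExemplarPool,
    ebm_predict_many,
)
from .task import N_CUES, CueProfile

__all__ = [
    "CUE_COLUMNS",
    "DATASET_COLUMNS",
    "JudgmentDataset",
    "FitOptions",
    "FitResult",
    "StrategyLabel",
    "RankDeficiencyError",
    "rmsd",
    "rmse_vs_criterion",
    "fit_cam",
    "fit_ebm",
    "loocv_rmsd",
    "projective_fit",
    "classify_strategy",
]

CUE_COLUMNS = [f"c{i+1}" for i in range(N_CUES)]
DATASET_COLUMNS = ["participant", "phase", "block", "role", *CUE_COLUMNS, "criterion", "response"]


class RankDeficiencyError(ValueError):
    """Cue design matrix is not full rank; names the offending dimensions."""


@dataclass
class JudgmentDataset:
    """Tabular judgment records (one row per judgment event).

    Columns: participant, phase, block, role, c1..c5, criterion, response.
    """

    frame: pd.DataFrame
    response_scale: tuple[int, int] = (0, 30)

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset missing column(s): {', '.join(missing)}")
        resp = self.frame["response"].to_numpy(dtype=float)
        if len(resp) and not np.all(np.isfinite(resp)):
            raise ValueError("responses must be finite")
        lo, hi = self.response_scale
        if len(resp) and (resp.min() < lo or resp.max() > hi):
            raise ValueError("responses outside the declared response scale")

    def participants(self) -> list:
        return sorted(self.frame["participant"].unique())

    def slice(self, participant=None, phase: str | None = None) -> pd.DataFrame:
        df = self.frame
        if participant is not None:
            df = df[df["participant"] == participant]
        if phase is not None:
            df = df[df["phase"] == phase]
        return df

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, response_scale: tuple[int, int] = (0, 30)) -> "JudgmentDataset":
        return cls(pd.read_csv(path), response_scale=response_scale)


@dataclass(frozen=True)
class FitOptions:
    """Estimation settings for the simplex-based EBM fit and cross-validation.

    ``restarts`` seeded Latin-hypercube starting points are used for a full
    fit; within LOOCV each fold additionally warm-starts at the full-data
    solution and runs ``fold_restarts`` fresh starts.  ``fold_unit`` chooses
    whether folds hold out unique items (default, matching the one-item-out
    description) or single judgment events.
    """

    restarts: int = 10
    fold_restarts: int = 2
    seed: int = 0
    fatol: float = 1e-8
    xatol: float = 1e-6
    maxiter: int = 2000
    fold_unit: Literal["item", "event"] = "item"
    average_repetitions: bool = False
    tie_tol: float = 1e-6


@dataclass
class FitResult:
    """A fitted model with its held-out or in-sample predictions and RMSD."""

    model_kind: Literal["CAM", "EBM"]
    params: CAMParams | EBMParams | list
    predictions: np.ndarray
    observations: np.ndarray
    rmsd: float
    regime: Literal["loocv", "projective", "plain"]
    converged: bool = True


@dataclass
class StrategyLabel:
    label: Literal["rule", "similarity", "tie"]
    rmsd_cam: float
    rmsd_ebm: float
    margin: float


def rmsd(predictions: Sequence[float], observations: Sequence[float]) -> float:
    """Root mean squared deviation between two equal-length vectors."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.size == 0 or p.shape != o.shape:
        raise ValueError("predictions and observations must be nonempty and equal-length")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def rmse_vs_criterion(records: pd.DataFrame) -> float:
    """Judgment accuracy: RMSD of responses against the true criteria."""
    if records["criterion"].isna().any():
        raise ValueError("records contain baseline items without criteria")
    return rmsd(records["response"].to_numpy(), records["criterion"].to_numpy())


def _design_matrix(profiles: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(profiles)), profiles])


def _diagnose_collinearity(profiles: np.ndarray) -> str:
    bad = []
    for i in range(N_CUES):
        if np.ptp(profiles[:, i]) == 0:
            bad.append(f"c{i+1} constant")
    for i in range(N_CUES):
        for j in range(i + 1, N_CUES):
            if np.ptp(profiles[:, i]) and np.ptp(profiles[:, j]):
                r = np.corrcoef(profiles[:, i], profiles[:, j])[0, 1]
                if abs(r) > 1 - 1e-12:
                    bad.append(f"c{i+1}~c{j+1} collinear")
    return "; ".join(bad) if bad else "cue design matrix rank-deficient"


def _profiles_responses(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = records[CUE_COLUMNS].to_numpy(dtype=float)
    y = records["response"].to_numpy(dtype=float)
    return X, y


def fit_cam(records: pd.DataFrame, options: FitOptions | None = None) -> CAMParams:
    """Analytic least-squares estimate of the CAM intercept and weights.

    Requires at least six distinct items and a full-rank cue design matrix;
    on noiseless CAM-generated full-rank data this recovers the generating
    parameters exactly.
    """
    X, y = _profiles_responses(records)
    distinct = np.unique(X, axis=0)
    if len(distinct) < N_CUES + 1:
        raise RankDeficiencyError(
            f"need >= {N_CUES + 1} distinct items to identify intercept + 5 weights, got {len(distinct)}"
        )
    D = _design_matrix(X)
    if np.linalg.matrix_rank(D) < N_CUES + 1:
        raise RankDeficiencyError(_diagnose_collinearity(X))
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return CAMParams(float(beta[0]), tuple(float(b) for b in beta[1:]))


def _ebm_loss_fn(X: np.ndarray, y: np.ndarray, pool: ExemplarPool):
    pool_profiles = pool.profiles
    pool_criteria = pool.criteria
    mism = X[:, None, :] != pool_profiles[None, :, :]

    def loss(s: np.ndarray) -> float:
        S = np.prod(np.where(mism, s[None, None, :], 1.0), axis=2)
        tot = S.sum(axis=1)
        if np.any(tot <= 0.0):
            return np.inf
        pred = S @ pool_criteria / tot
        return float(np.sum((pred - y) ** 2))

    return loss


_LOGIT_CLIP = 1e-9
# identifiability floor for fitted similarities: below this the model is
# behaviorally at its exact-match-retrieval limit, and exact zeros would make
# predictions for unseen probes undefined
_S_FLOOR = 1e-6


def fit_ebm(
    records: pd.DataFrame,
    pool: ExemplarPool,
    options: FitOptions | None = None,
    starts: Sequence[Sequence[float]] | None = None,
) -> EBMParams:
    """Simplex estimate of the EBM similarity parameters s_1..s_5.

    The [0, 1] box constraint is handled by optimizing an unconstrained
    logistic reparameterization u = logit(s) with Nelder-Mead, taking the
    best of ``options.restarts`` Latin-hypercube starting points.  The upper
    boundary s = (1,...,1) is always evaluated as a candidate, so the
    returned loss never exceeds the mean-prediction baseline; exact zeros are
    never returned (s can only approach the exact-match-retrieval limit), so
    fitted parameters always yield well-defined predictions for new probes.
    """
    opts = options or FitOptions()
    X, y = _profiles_responses(records)
    if len(y) < 6:
        raise ValueError(f"need >= 6 observations to fit 5 similarity parameters, got {len(y)}")
    loss = _ebm_loss_fn(X, y, pool)

    if starts is None:
        sampler = qmc.LatinHypercube(d=N_CUES, seed=opts.seed)
        starts = qmc.scale(sampler.random(max(1, opts.restarts)), 0.05, 0.95)
    else:
        starts = np.asarray(starts, dtype=float)

    best_s, best_loss, any_converged = None, np.inf, False
    for s0 in starts:
        u0 = logit(np.clip(s0, _LOGIT_CLIP, 1 - _LOGIT_CLIP))
        res = minimize(
            lambda u: loss(np.clip(expit(u), _S_FLOOR, 1.0)),
            u0,
            method="Nelder-Mead",
            options={"fatol": opts.fatol, "xatol": opts.xatol, "maxiter": opts.maxiter},
        )
        any_converged = any_converged or bool(res.success)
        if res.fun < best_loss:
            best_loss, best_s = res.fun, np.clip(expit(res.x), _S_FLOOR, 1.0)

    # the upper corner (uniform similarity = pool-mean prediction) is always a
    # candidate, guaranteeing the fit never loses to that baseline; exact
    # zeros are never produced by the optimizer, keeping predictions for
    # unseen probes well defined (s -> 0 approaches exact-match retrieval)
    ones = np.ones(N_CUES)
    if loss(ones) < best_loss:
        best_loss, best_s = loss(ones), ones
    snapped = np.where(best_s > 1 - _LOGIT_CLIP * 10, 1.0, best_s)
    if loss(snapped) <= best_loss + 1e-9:
        best_s = snapped
    if not any_converged:
        warnings.warn("EBM simplex search did not report convergence from any restart", RuntimeWarning)
    return EBMParams(tuple(float(v) for v in np.clip(best_s, 0.0, 1.0)))


def _predict(model_kind: str, params, pool: ExemplarPool | None, X: np.ndarray) -> np.ndarray:
    if model_kind == "CAM":
        return params.intercept + X @ np.asarray(params.weights)
    profiles = [CueProfile(tuple(int(v) for v in row)) for row in X]
    return ebm_predict_many(params, pool, profiles)


def _fit_one(model_kind: str, records: pd.DataFrame, pool, opts: FitOptions, starts=None):
    if model_kind == "CAM":
        return fit_cam(records, opts)
    return fit_ebm(records, pool, opts, starts=starts)


def _maybe_average(records: pd.DataFrame, opts: FitOptions) -> pd.DataFrame:
    if not opts.average_repetitions:
        return records
    grouped = (
        records.groupby(CUE_COLUMNS, as_index=False)
        .agg({"response": "mean", "criterion": "first"})
    )
    return grouped


def loocv_rmsd(
    model_kind: Literal["CAM", "EBM"],
    records: pd.DataFrame,
    pool: ExemplarPool | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Leave-one-out cross-validated RMSD for one participant's records.

    One fold per unique item (or per event, per ``options.fold_unit``);
    parameters are re-estimated on the remaining records in each fold and
    scored only on the held-out responses.  Deterministic given
    ``options.seed``.
    """
    opts = options or FitOptions()
    records = _maybe_average(records.reset_index(drop=True), opts)
    n = len(records)
    if n < 7:
        raise ValueError(f"LOOCV needs >= 7 observations, got {n}")
    X, y = _profiles_responses(records)

    if opts.fold_unit == "item":
        _, fold_ids = np.unique(X, axis=0, return_inverse=True)
    else:
        fold_ids = np.arange(n)
    n_folds = fold_ids.max() + 1

    warm_starts = None
    if model_kind == "EBM":
        full = fit_ebm(records, pool, opts)
        sampler = qmc.LatinHypercube(d=N_CUES, seed=opts.seed + 1)
        extra = qmc.scale(sampler.random(max(1, opts.fold_restarts)), 0.05, 0.95)
        warm_starts = np.vstack([np.clip(full.similarities, 0.01, 0.99), extra])

    preds = np.empty(n)
    per_fold_params = []
    converged = True
    for f in range(n_folds):
        held = fold_ids == f
        train = records.loc[~held]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            params = _fit_one(model_kind, train, pool, opts, starts=warm_starts)
            if any(issubclass(w.category, RuntimeWarning) for w in caught):
                converged = False
        per_fold_params.append(params)
        preds[held] = _predict(model_kind, params, pool, X[held])
    return FitResult(
        model_kind=model_kind,
        params=per_fold_params,
        predictions=preds,
        observations=y,
        rmsd=rmsd(preds, y),
        regime="loocv",
        converged=converged,
    )


def projective_fit(
    model_kind: Literal["CAM", "EBM"],
    training_records: pd.DataFrame,
    test_records: pd.DataFrame,
    pool: ExemplarPool | None = None,
    options: FitOptions | None = None,
    n_blocks: int = 3,
) -> FitResult:
    """Estimate on the last ``n_blocks`` training blocks, score on test items.

    Parameters are frozen after estimation; the reported RMSD is computed on
    the test-phase responses only.
    """
    opts = options or FitOptions()
    blocks = np.sort(training_records["block"].unique())
    if len(blocks) < n_blocks:
        raise ValueError(f"projective fit needs >= {n_blocks} training blocks, got {len(blocks)}")
    late = training_records[training_records["block"].isin(blocks[-n_blocks:])]
    params = _fit_one(model_kind, late, pool, opts)
    X, y = _profiles_responses(test_records)
    preds = _predict(model_kind, params, pool, X)
    return FitResult(
        model_kind=model_kind,
        params=params,
        predictions=preds,
        observations=y,
        rmsd=rmsd(preds, y),
        regime="projective",
    )


def plain_fit(
    model_kind: Literal["CAM", "EBM"],
    records: pd.DataFrame,
    pool: ExemplarPool | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """In-sample fit: estimate and score on the same records."""
    opts = options or FitOptions()
    params = _fit_one(model_kind, records, pool, opts)
    X, y = _profiles_responses(records)
    preds = _predict(model_kind, params, pool, X)
    return FitResult(model_kind, params, preds, y, rmsd(preds, y), "plain")


def classify_strategy(
    fit_cam_result: FitResult, fit_ebm_result: FitResult, tie_tol: float = 1e-6
) -> StrategyLabel:
    """Label a participant by which model attains the smaller RMSD."""
    if fit_cam_result.model_kind != "CAM" or fit_ebm_result.model_kind != "EBM":
        raise ValueError("expected one CAM FitResult and one EBM FitResult")
    a, b = fit_cam_result.observations, fit_ebm_result.observations
    if a.shape != b.shape or not np.allclose(a, b):
        raise ValueError("fits were scored on different observation sets")
    d = fit_cam_result.rmsd - fit_ebm_result.rmsd
    if abs(d) <= tie_tol:
        label = "tie"
    else:
        label = "rule" if d < 0 else "similarity"
    return StrategyLabel(label, fit_cam_result.rmsd, fit_ebm_result.rmsd, margin=abs(d))
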