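"""Bootstrapped penalized regression with selection-frequency thresholding.

The engine behind every cell of the model grid: resample participants with
replacement B times (B scales linearly with the model's sample size, clamped
to [20, 70]), fit an L1- or elastic-net-penalized model per replicate with
the penalty weight chosen by internal cross-validation, count how often each
feature receives a nonzero coefficient, keep the features whose count exceeds
the threshold (mean of the maximum count and the third quartile of all
counts), and report their averaged coefficients with percentile confidence
intervals.

Penalized fits are delegated to scikit-learn.  Forced covariates (baseline
sarcopenia status) are unpenalized: for squared-error loss they are profiled
out exactly by least-squares residualization before the lasso (the profiled
problem is exactly the lasso with unpenalized covariates); for logistic loss
the forced column is rescaled by a large factor so its effective L1 penalty
is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.linear_model import (
    ElasticNet,
    ElasticNetCV,
    Lasso,
    LassoCV,
    LogisticRegression,
    LogisticRegressionCV,
)
from sklearn.model_selection import KFold, StratifiedKFold

#: |coefficient| above which a feature counts as selected; lasso paths give
#: exact zeros, the tolerance only guards float dust.
SELECTION_TOL = 1e-8

#: Effective penalty on forced covariates in logistic fits is 1/_FORCED_SCALE
#: of the common penalty.
_FORCED_SCALE = 100.0

#: Per-sample penalty-weight grid searched by cross-validation in
#: classification fits (regression uses scikit-learn's data-driven path).
_LAMBDA_GRID_CLS = np.logspace(-3.0, 0.5, 10)

VARIANTS = ("all_data", "biomarker_subset")
OUTCOMES = ("SarcAny", "Echo", "BATT", "SMMSergi")
HORIZONS = ("d7", "w13")
PREDICTOR_TIMEPOINTS = ("preop", "h48", "d7", "w13")


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the model grid."""

    variant: str
    outcome: str
    outcome_horizon: str
    predictor_timepoint: str
    penalty: str = "lasso"
    mixing: float = 1.0  # elastic-net L1 fraction; 1.0 is the lasso

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome_horizon not in HORIZONS:
            raise ValueError(f"unknown horizon {self.outcome_horizon!r}")
        if self.predictor_timepoint not in PREDICTOR_TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.predictor_timepoint!r}")
        if self.penalty not in ("lasso", "elastic_net"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        if not 0.0 < self.mixing <= 1.0:
            raise ValueError("mixing must lie in (0, 1]")
        if self.penalty == "lasso" and self.mixing != 1.0:
            raise ValueError("mixing must be 1.0 for the lasso")

    @property
    def task(self) -> str:
        return "classification" if self.outcome == "SarcAny" else "regression"

    @property
    def retrodictive(self) -> bool:
        """Predictors measured at or after the outcome horizon."""
        order = {tp: i for i, tp in enumerate(PREDICTOR_TIMEPOINTS)}
        return order[self.predictor_timepoint] >= order[self.outcome_horizon]

    def label(self) -> str:
        return (f"{self.variant}:{self.outcome}@{self.outcome_horizon}"
                f"~{self.predictor_timepoint}")


@dataclass
class SelectionSummary:
    """Averaged coefficient of one retained feature (standardized scale)."""

    feature: str
    mean_coefficient: float
    ci_low: float
    ci_high: float
    selected_count: int
    n_replicates: int


@dataclass
class BootstrapResult:
    """Selection counts and coefficient draws for one fitted model spec."""

    spec: ModelSpec
    n_rows: int
    n_replicates: int
    selection_counts: dict[str, int]
    coefficient_draws: dict[str, list[float]]
    forced_coefficients: dict[str, list[float]]
    seeds: list[int]
    n_discarded: int = 0

    @property
    def unstable(self) -> bool:
        """More than 20% of replicates were discarded as degenerate."""
        return self.n_discarded > 0.2 * self.n_replicates


def replicate_count(n_rows: int, b_min: int = 20, b_max: int = 70,
                    n_min: int = 10, n_max: int = 79) -> int:
    """Bootstrap replicates for a model of ``n_rows`` participants.

    Linear in the sample size between the anchors and clamped to
    [``b_min``, ``b_max``]; the full cohort (79) maps to 70 replicates and
    any model of 10 or fewer rows to 20.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    frac = (n_rows - n_min) / (n_max - n_min)
    b = int(round(b_min + (b_max - b_min) * frac))
    return max(b_min, min(b_max, b))


def _cv_folds(n_rows: int, n_folds: int) -> int:
    if n_rows >= n_folds:
        return n_folds
    return max(2, n_rows - 1)


def fit_penalized(
    X: np.ndarray,
    y: np.ndarray,
    *,
    task: str,
    penalty: str = "lasso",
    mixing: float = 1.0,
    forced_idx: Sequence[int] = (),
    lambda_: Optional[float] = None,
    seed: int = 0,
    n_folds: int = 5,
    lambda_rule: str = "min",
) -> tuple[np.ndarray, float]:
    """Fit one penalized model; returns (coefficients, intercept).

    ``lambda_`` is the per-sample penalty weight (scikit-learn's ``alpha``
    for squared error; ``1/(C n)`` for logistic loss).  When ``None`` it is
    chosen by k-fold cross-validation with seeded folds: at the loss minimum
    (``lambda_rule="min"``, the default) or as the largest penalty within one
    standard error of the minimum (``"1se"``, sparser).  Unselected features
    come back as exact zeros; forced columns carry (effectively) no penalty.
    """
    if lambda_rule not in ("min", "1se"):
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    forced_idx = list(forced_idx)
    pen_idx = [j for j in range(p) if j not in forced_idx]
    coefs = np.zeros(p)
    k = _cv_folds(n, n_folds)

    if task == "regression":
        # profile out intercept + forced covariates exactly
        Z = np.column_stack([np.ones(n)] + [X[:, j] for j in forced_idx])
        stacked = np.column_stack([X[:, pen_idx], y]) if pen_idx else y[:, None]
        gamma_all, *_ = np.linalg.lstsq(Z, stacked, rcond=None)
        resid = stacked - Z @ gamma_all
        if pen_idx:
            Xt, yt = resid[:, :-1], resid[:, -1]
            l1_ratio = mixing if penalty == "elastic_net" else 1.0
            if lambda_ is None:
                cv = KFold(n_splits=k, shuffle=True, random_state=seed)
                if penalty == "lasso":
                    model = LassoCV(cv=cv, alphas=30, fit_intercept=False,
                                    max_iter=20_000)
                else:
                    model = ElasticNetCV(l1_ratio=l1_ratio, cv=cv, alphas=30,
                                         fit_intercept=False, max_iter=20_000)
            elif penalty == "lasso":
                model = Lasso(alpha=lambda_, fit_intercept=False, max_iter=50_000)
            else:
                model = ElasticNet(alpha=lambda_, l1_ratio=l1_ratio,
                                   fit_intercept=False, max_iter=50_000)
            model.fit(Xt, yt)
            if lambda_ is None and lambda_rule == "1se":
                mean = model.mse_path_.mean(axis=1)
                se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(
                    model.mse_path_.shape[1])
                i_min = int(np.argmin(mean))
                ok = np.flatnonzero(mean <= mean[i_min] + se[i_min])
                alpha_1se = float(model.alphas_[ok.min()])  # alphas descend
                if penalty == "lasso":
                    model = Lasso(alpha=alpha_1se, fit_intercept=False,
                                  max_iter=50_000)
                else:
                    model = ElasticNet(alpha=alpha_1se, l1_ratio=l1_ratio,
                                       fit_intercept=False, max_iter=50_000)
                model.fit(Xt, yt)
            beta = model.coef_
            coefs[pen_idx] = np.where(np.abs(beta) > SELECTION_TOL, beta, 0.0)
        # forced coefficients by OLS on the partial residual
        resid_y = y - X[:, pen_idx] @ coefs[pen_idx] if pen_idx else y
        gamma, *_ = np.linalg.lstsq(Z, resid_y, rcond=None)
        intercept = float(gamma[0])
        for i, j in enumerate(forced_idx):
            coefs[j] = float(gamma[i + 1])
        return coefs, intercept

    if task != "classification":
        raise ValueError(f"unknown task {task!r}")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("single-class outcome")
    Xs = X.copy()
    if forced_idx:
        Xs[:, forced_idx] *= _FORCED_SCALE
    solver = "liblinear" if penalty == "lasso" else "saga"
    l1r = 1.0 if penalty == "lasso" else mixing

    def _fit_at(lam: float, Xf: np.ndarray, yf: np.ndarray) -> LogisticRegression:
        model = LogisticRegression(
            C=1.0 / (len(yf) * lam), l1_ratio=l1r, solver=solver,
            fit_intercept=True, tol=1e-6, max_iter=10_000, random_state=seed)
        model.fit(Xf, yf)
        return model

    if lambda_ is None:
        min_class = int(np.bincount(y.astype(int)).min())
        k = min(k, min_class)
        if k < 2:
            raise ValueError("too few members in the minority class for CV")
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        losses = np.zeros((k, _LAMBDA_GRID_CLS.size))
        for fi, (tr, te) in enumerate(cv.split(Xs, y)):
            for gi, lam in enumerate(_LAMBDA_GRID_CLS):
                m = _fit_at(lam, Xs[tr], y[tr])
                prob = np.clip(m.predict_proba(Xs[te])[:, 1], 1e-12, 1 - 1e-12)
                losses[fi, gi] = -np.mean(y[te] * np.log(prob)
                                          + (1 - y[te]) * np.log(1 - prob))
        mean = losses.mean(axis=0)
        # ties broken toward the larger (sparser) penalty; grid ascends
        best = int(mean.size - 1 - np.argmin(mean[::-1]))
        if lambda_rule == "1se":
            se = losses.std(axis=0, ddof=1) / np.sqrt(k)
            ok = np.flatnonzero(mean <= mean[best] + se[best])
            best = int(ok.max())
        lambda_ = float(_LAMBDA_GRID_CLS[best])
    model = _fit_at(lambda_, Xs, y)
    beta, intercept = model.coef_[0].copy(), float(model.intercept_[0])
    if forced_idx:
        beta[forced_idx] *= _FORCED_SCALE  # back to the unscaled column
    for j in range(p):
        coefs[j] = beta[j] if (j in forced_idx or abs(beta[j]) > SELECTION_TOL) else 0.0
    return coefs, intercept


def _resample_indices(rng: np.random.Generator, y: np.ndarray, task: str,
                      stratify: bool) -> np.ndarray:
    n = y.shape[0]
    if task == "classification" and stratify:
        parts = []
        for cls in np.unique(y):
            members = np.flatnonzero(y == cls)
            parts.append(rng.choice(members, size=members.size, replace=True))
        return np.concatenate(parts)
    return rng.integers(0, n, size=n)


def bootstrap_select(table, spec: ModelSpec, master_seed: int,
                     stratify: bool = True, n_folds: int = 5,
                     lambda_rule: str = "min") -> BootstrapResult:
    """Run the full bootstrap for one model spec on a preprocessed table.

    Resamples rows with replacement (stratified by outcome class for
    classification, to avoid single-class replicates), refits the penalized
    model per replicate with seeded internal CV, and records every feature
    with a nonzero coefficient together with its coefficient draw.
    Deterministic given ``master_seed``.
    """
    n = table.n_rows
    B = replicate_count(n)
    X = table.X.to_numpy(dtype=float)
    y = table.y.to_numpy(dtype=float)
    cols = list(table.X.columns)
    forced_idx = [cols.index(c) for c in table.forced]
    pen_cols = [c for c in cols if c not in table.forced]

    rng = np.random.default_rng(np.random.SeedSequence([master_seed & 0x7FFFFFFF, 11]))
    counts = {c: 0 for c in pen_cols}
    draws: dict[str, list[float]] = {c: [] for c in pen_cols}
    forced_draws: dict[str, list[float]] = {c: [] for c in table.forced}
    seeds: list[int] = []
    discarded = 0
    for _ in range(B):
        fit_seed = int(rng.integers(2**31 - 1))
        idx = _resample_indices(rng, y, spec.task, stratify)
        yb = y[idx]
        if spec.task == "classification" and np.unique(yb).size < 2:
            discarded += 1
            continue
        try:
            coefs, _ = fit_penalized(
                X[idx], yb, task=spec.task, penalty=spec.penalty,
                mixing=spec.mixing, forced_idx=forced_idx, seed=fit_seed,
                n_folds=n_folds, lambda_rule=lambda_rule)
        except (ValueError, np.linalg.LinAlgError):
            discarded += 1
            continue
        seeds.append(fit_seed)
        for j, c in zip((j for j in range(len(cols)) if j not in forced_idx), pen_cols):
            if abs(coefs[j]) > SELECTION_TOL:
                counts[c] += 1
                draws[c].append(float(coefs[j]))
        for i, c in zip(forced_idx, table.forced):
            forced_draws[c].append(float(coefs[i]))
    return BootstrapResult(
        spec=spec, n_rows=n, n_replicates=B, selection_counts=counts,
        coefficient_draws=draws, forced_coefficients=forced_draws,
        seeds=seeds, n_discarded=discarded)


def selection_threshold(counts) -> float:
    """(max + Q3) / 2 over the selection counts of the penalized features.

    Q3 uses linear interpolation at position 0.75 * (m - 1) on the sorted
    counts.  The threshold therefore always lies in [Q3, max].
    """
    if isinstance(counts, Mapping):
        counts = list(counts.values())
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        raise ValueError("counts must be non-empty")
    q3 = float(np.percentile(arr, 75, method="linear"))
    return (float(arr.max()) + q3) / 2.0


def summarize_selected(result: BootstrapResult) -> list[SelectionSummary]:
    """Summaries for features whose count is strictly above the threshold.

    Mean over the nonzero replicate coefficients; 95% CI from the 2.5th and
    97.5th percentiles of those draws, or [min, max] when fewer than four
    draws exist.  Sorted by |mean coefficient| descending (feature name as
    tie-break) so output order is deterministic.
    """
    if not result.selection_counts:
        return []
    thr = selection_threshold(result.selection_counts)
    out = []
    for feature, count in result.selection_counts.items():
        if count <= thr:
            continue
        d = np.asarray(result.coefficient_draws[feature], dtype=float)
        mean = float(d.mean())
        if d.size < 4:
            lo, hi = float(d.min()), float(d.max())
        else:
            lo, hi = (float(v) for v in np.percentile(d, [2.5, 97.5]))
        out.append(SelectionSummary(
            feature=feature, mean_coefficient=mean, ci_low=lo, ci_high=hi,
            selected_count=int(count), n_replicates=result.n_replicates))
    out.sort(key=lambda s: (-abs(s.mean_coefficient), s.feature))
    return out
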