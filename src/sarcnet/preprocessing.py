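"""Turn a tidy cohort into a model-ready feature table.

For one cell of the model grid this module restricts rows to the relevant
analysis variant, gathers constant predictors (demographics, comorbidity and
medication flags) plus the measurements of the predictor timepoint, attaches
the outcome (sarcopenia status at the horizon, or signed change from baseline
for the continuous muscle outcomes), then applies the published preprocessing
order: delete features with >= 30% missing values, impute the remainder with
the median (numeric) or mode (categorical/binary), and standardize.

The baseline sarcopenia status is attached as a *forced* covariate: it is
exempt from the missingness filter, from constant-column dropping and (in the
selection engine) from penalization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import (
    BIO_PREFIX,
    COND_PREFIX,
    MED_PREFIX,
    PANEL_FIELDS,
    TIMEPOINT_ORDER,
    TIMEPOINTS,
    add_derived_columns,
)

FORCED_BASELINE = "sarc_baseline"

#: Per-timepoint measurement predictors (raw fields plus derived quantities).
MEASUREMENT_PREDICTORS = tuple(
    f for f in PANEL_FIELDS if f not in ("rf_right_cm", "vi_right_cm",
                                         "rf_left_cm", "vi_left_cm", "height_cm")
) + ("batt_cm", "smm_sergi_kg")


class EmptyTableError(ValueError):
    """No usable rows or columns remain for a model."""


@dataclass
class VariantSpec:
    """Analysis variant and its missingness-deletion threshold.

    ``all_data`` keeps every participant and deletes any feature with a
    missing fraction at or above 0.30 before imputing.  ``biomarker_subset``
    restricts rows to participants with systemic biomarker data and imputes
    everything, deleting only columns that are entirely missing.
    """

    variant: str = "all_data"
    missing_threshold: float = 0.30

    def __post_init__(self) -> None:
        if self.variant not in ("all_data", "biomarker_subset"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 < self.missing_threshold <= 1.0:
            raise ValueError("missing_threshold must lie in (0, 1]")


def default_variant_spec(variant: str) -> VariantSpec:
    return VariantSpec(variant=variant,
                       missing_threshold=0.30 if variant == "all_data" else 1.0)


@dataclass
class FeatureTable:
    """Predictors, outcome and bookkeeping for one model."""

    X: pd.DataFrame
    y: pd.Series
    task: str  # "classification" | "regression"
    forced: list[str]
    kinds: dict[str, str]  # column -> "numeric" | "binary"
    provenance: dict = field(default_factory=dict)
    scaling: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.X)


def compute_change_outcome(value_at_horizon, value_at_baseline):
    """Signed change, horizon minus baseline; NaN when either is missing."""
    if pd.isna(value_at_horizon) or pd.isna(value_at_baseline):
        return float("nan")
    return float(value_at_horizon) - float(value_at_baseline)


def participants_with_biomarkers(frame: pd.DataFrame) -> set[str]:
    """Participants with any systemic biomarker value at preop or 48 h."""
    bio_cols = [c for c in frame.columns if c.startswith(BIO_PREFIX)]
    if not bio_cols:
        return set()
    sub = frame[frame["timepoint"].isin(["preop", "h48"])]
    has = sub[bio_cols].notna().any(axis=1)
    return set(sub.loc[has, "participant_id"])


def _outcome_column(outcome: str) -> str:
    return {"SarcAny": "sarc_status", "Echo": "echogenicity_gsu",
            "BATT": "batt_cm", "SMMSergi": "smm_sergi_kg"}[outcome]


def assemble_table(frame: pd.DataFrame, model_spec) -> FeatureTable:
    """Build the raw (pre-filter) feature table for one model spec.

    Rows: participants who attended the predictor timepoint, whose outcome at
    the horizon is observed, and whose baseline sarcopenia status is known.
    Columns: constants + predictor-timepoint measurements (+ biomarkers when
    the predictor timepoint is preop/48 h), suffixed ``@<timepoint>``.
    """
    if model_spec.predictor_timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown predictor timepoint {model_spec.predictor_timepoint!r}")
    if model_spec.outcome_horizon not in ("d7", "w13"):
        raise ValueError(f"unknown outcome horizon {model_spec.outcome_horizon!r}")
    frame = add_derived_columns(frame)
    tp = model_spec.predictor_timepoint
    horizon = model_spec.outcome_horizon

    by_pid: dict[str, pd.DataFrame] = {
        pid: sub.set_index("timepoint") for pid, sub in frame.groupby("participant_id", sort=True)
    }
    allowed = None
    if model_spec.variant == "biomarker_subset":
        allowed = participants_with_biomarkers(frame)

    outcome_col = _outcome_column(model_spec.outcome)
    flag_cols = [c for c in frame.columns if c.startswith((COND_PREFIX, MED_PREFIX))]
    bio_cols = [c for c in frame.columns if c.startswith(BIO_PREFIX)]
    eth_levels = list(dict.fromkeys(frame["ethnicity"]))
    smoke_levels = list(dict.fromkeys(frame["smoking"]))

    rows, ys, index = [], [], []
    n_no_visit = n_no_outcome = n_no_baseline = 0
    for pid, sub in by_pid.items():
        if allowed is not None and pid not in allowed:
            continue
        if tp not in sub.index:
            n_no_visit += 1
            continue
        baseline_tp = next((t for t in TIMEPOINTS if t in sub.index), None)
        visit = sub.loc[tp]
        base = sub.loc[baseline_tp]
        if model_spec.outcome == "SarcAny":
            v = sub.loc[horizon, outcome_col] if horizon in sub.index else float("nan")
            y = float("nan") if pd.isna(v) else float(v)
        else:
            vh = sub.loc[horizon, outcome_col] if horizon in sub.index else float("nan")
            y = compute_change_outcome(vh, base[outcome_col])
        if pd.isna(y):
            n_no_outcome += 1
            continue
        s0 = base["sarc_status"]
        if pd.isna(s0):
            n_no_baseline += 1
            continue
        row: dict[str, float] = {
            "age": float(visit["age"]),
            "sex_male": 1.0 if visit["sex"] == "male" else 0.0,
        }
        for lvl in eth_levels[1:]:
            row[f"ethnicity={lvl}"] = 1.0 if visit["ethnicity"] == lvl else 0.0
        for lvl in smoke_levels[1:]:
            row[f"smoking={lvl}"] = 1.0 if visit["smoking"] == lvl else 0.0
        for c in flag_cols:
            row[c] = float(visit[c]) if not pd.isna(visit[c]) else float("nan")
        for c in MEASUREMENT_PREDICTORS:
            row[f"{c}@{tp}"] = float(visit[c]) if not pd.isna(visit[c]) else float("nan")
        if tp in ("preop", "h48"):
            for c in bio_cols:
                row[f"{c}@{tp}"] = float(visit[c]) if not pd.isna(visit[c]) else float("nan")
        row[FORCED_BASELINE] = float(s0)
        rows.append(row)
        ys.append(float(y))
        index.append(pid)

    if not rows:
        raise EmptyTableError(
            f"no usable rows for predictors@{tp} -> {model_spec.outcome}@{horizon} "
            f"({n_no_visit} missing visit, {n_no_outcome} missing outcome, "
            f"{n_no_baseline} missing baseline status)"
        )
    X = pd.DataFrame(rows, index=index)
    y = pd.Series(ys, index=index, name=f"{model_spec.outcome}@{horizon}")
    kinds = {}
    for col in X.columns:
        if (col.startswith((COND_PREFIX, MED_PREFIX)) or col == "sex_male"
                or col == FORCED_BASELINE or "=" in col):
            kinds[col] = "binary"
        else:
            kinds[col] = "numeric"
    task = "classification" if model_spec.outcome == "SarcAny" else "regression"
    prov = {"n_rows": len(X),
            "excluded": {"missing_visit": n_no_visit,
                         "missing_outcome": n_no_outcome,
                         "missing_baseline_status": n_no_baseline}}
    return FeatureTable(X=X, y=y, task=task, forced=[FORCED_BASELINE],
                        kinds=kinds, provenance=prov)


def filter_missingness(table: FeatureTable, threshold: float = 0.30) -> FeatureTable:
    """Delete non-forced columns whose missing fraction is >= threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    frac = table.X.isna().mean()
    deleted = {c: float(frac[c]) for c in table.X.columns
               if c not in table.forced and frac[c] >= threshold}
    kept = [c for c in table.X.columns if c not in deleted]
    if all(c in table.forced for c in kept):
        raise EmptyTableError("missingness filter removed every penalized column")
    prov = dict(table.provenance)
    prov["deleted_features"] = deleted
    prov["missing_threshold"] = threshold
    return replace(table, X=table.X[kept],
                   kinds={c: table.kinds[c] for c in kept}, provenance=prov)


def _column_mode(values: pd.Series):
    """Most frequent observed value; ties broken by first appearance."""
    counts = Counter(v for v in values if not pd.isna(v))
    if not counts:
        raise EmptyTableError(f"column {values.name!r} is entirely missing")
    best = max(counts.values())
    for v in values:
        if not pd.isna(v) and counts[v] == best:
            return v
    raise AssertionError("unreachable")


def impute(table: FeatureTable) -> FeatureTable:
    """Median-impute numeric columns, mode-impute binary/categorical ones."""
    X = table.X.copy()
    constants: dict[str, float] = {}
    for col in X.columns:
        if not X[col].isna().any():
            continue
        if X[col].notna().sum() == 0:
            raise EmptyTableError(f"column {col!r} is entirely missing; filter first")
        if table.kinds[col] == "binary":
            fill = _column_mode(X[col])
        else:
            fill = float(X[col].median())  # even counts: midpoint of central pair
        constants[col] = float(fill)
        X[col] = X[col].fillna(fill)
    prov = dict(table.provenance)
    prov["imputation_constants"] = constants
    return replace(table, X=X, provenance=prov)


def standardize(table: FeatureTable) -> FeatureTable:
    """Center/scale predictors to mean 0, SD 1; drop constant columns.

    Binary columns are standardized too so every predictor pays the same
    penalty per standardized unit.  Zero-variance columns are dropped unless
    forced (a constant forced column is kept unscaled).  For regression tasks
    the outcome is standardized as well; the scaling record allows exact
    back-transformation of coefficients to raw scale.
    """
    if table.X.isna().any().any():
        raise ValueError("standardize requires an imputed table")
    X = table.X.copy()
    scaling: dict[str, tuple[float, float]] = {}
    dropped: list[str] = []
    for col in list(X.columns):
        mean = float(X[col].mean())
        sd = float(X[col].std(ddof=0))
        if sd <= 1e-12:
            if col in table.forced:
                scaling[col] = (0.0, 1.0)  # constant forced column kept as-is
            else:
                dropped.append(col)
                X = X.drop(columns=[col])
            continue
        scaling[col] = (mean, sd)
        X[col] = (X[col] - mean) / sd
    if not any(c not in table.forced for c in X.columns):
        raise EmptyTableError("no penalized predictors left after dropping constants")
    y = table.y.copy()
    if table.task == "regression":
        y_mean = float(y.mean())
        y_sd = float(y.std(ddof=0))
        if y_sd <= 1e-12:
            raise EmptyTableError("outcome has zero variance")
        y = (y - y_mean) / y_sd
        scaling["__outcome__"] = (y_mean, y_sd)
    prov = dict(table.provenance)
    prov["dropped_constant"] = dropped
    kinds = {c: table.kinds[c] for c in X.columns}
    return replace(table, X=X, y=y, kinds=kinds, provenance=prov, scaling=scaling)


def preprocess(table: FeatureTable, threshold: float = 0.30) -> FeatureTable:
    """filter -> impute -> standardize, the published order."""
    return standardize(impute(filter_missingness(table, threshold)))


def unscale_coefficient(table: FeatureTable, column: str, coef: float) -> float:
    """Map a standardized-scale coefficient back to raw units."""
    _, x_sd = table.scaling[column]
    y_sd = table.scaling.get("__outcome__", (0.0, 1.0))[1]
    return coef * y_sd / x_sd


def missingness_matrix(frame: pd.DataFrame) -> pd.DataFrame:
    """Fraction of missing cells per (feature, timepoint); mirrors a
    missing-data heatmap over the raw cohort."""
    cols = [c for c in frame.columns if c in PANEL_FIELDS or c.startswith(BIO_PREFIX)]
    out = frame.groupby("timepoint", sort=False)[cols].apply(lambda d: d.isna().mean())
    return out.reindex([tp for tp in TIMEPOINTS if tp in out.index]).T
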