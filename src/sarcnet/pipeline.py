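"""Model-grid enumeration, orchestration, reporting.

The default grid crosses 2 analysis variants x 4 outcomes (sarcopenia status,
echogenicity, BATT, Sergi SMM) x 2 outcome horizons (7 days, 13 weeks) x 4
predictor timepoints = 64 models.  Each model is assembled, filtered, imputed,
standardized, bootstrapped and summarized; the run then writes a Table-2-style
CSV of retained associations, per-model JSON results, figure-style networks,
a missingness matrix, a provenance log and a manifest sufficient to re-run
bit-identically.  A model whose predictor timepoint is not strictly earlier
than its outcome horizon is still fitted when configured but flagged
retrodictive.  Model-level failures (for instance an empty table after
filtering) are logged and skipped; the run fails only if every model fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy import stats

from . import __version__
from .cohort import BIO_PREFIX, read_cohort_csv
from .network import FIGURE_STRATA, Stratum, build_network, export_network
from .preprocessing import (
    EmptyTableError,
    assemble_table,
    missingness_matrix,
    preprocess,
)
from .selection import (
    HORIZONS,
    OUTCOMES,
    PREDICTOR_TIMEPOINTS,
    VARIANTS,
    BootstrapResult,
    ModelSpec,
    SelectionSummary,
    bootstrap_select,
    selection_threshold,
    summarize_selected,
)
from .simulate import SimConfig, generate_frame

log = logging.getLogger("sarcnet")


class GridConfig(BaseModel):
    """Axes of the model grid; the default product is 64."""

    variants: list[str] = Field(default_factory=lambda: list(VARIANTS))
    outcomes: list[str] = Field(default_factory=lambda: list(OUTCOMES))
    horizons: list[str] = Field(default_factory=lambda: list(HORIZONS))
    predictor_timepoints: list[str] = Field(
        default_factory=lambda: list(PREDICTOR_TIMEPOINTS))
    penalty: str = "lasso"
    mixing: float = 1.0

    @field_validator("variants", "outcomes", "horizons", "predictor_timepoints")
    @classmethod
    def _axis(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("grid axis must be non-empty")
        if len(set(v)) != len(v):
            raise ValueError(f"duplicate axis entries: {v}")
        return v


class PipelineConfig(BaseModel):
    """Everything one run needs; validated before any computation."""

    seed: int = 0
    cohort_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    grid: GridConfig = Field(default_factory=GridConfig)
    #: Missingness-deletion threshold per analysis variant.
    missing_thresholds: dict[str, float] = Field(
        default_factory=lambda: {"all_data": 0.30, "biomarker_subset": 1.0})
    stratify_bootstrap: bool = True
    cv_folds: int = 5
    #: Penalty-weight choice within each bootstrap fit: "min" (loss minimum)
    #: or "1se" (sparser, one standard error above the minimum).
    lambda_rule: Literal["min", "1se"] = "min"

    @field_validator("missing_thresholds")
    @classmethod
    def _thr(cls, v: dict[str, float]) -> dict[str, float]:
        for name, t in v.items():
            if not 0.0 < t <= 1.0:
                raise ValueError(f"threshold for {name!r} must lie in (0, 1]")
        return v


def enumerate_model_grid(config: PipelineConfig) -> list[ModelSpec]:
    """Deterministic grid order: variant, outcome, horizon, predictor timepoint."""
    g = config.grid
    specs = [
        ModelSpec(variant=v, outcome=o, outcome_horizon=h,
                  predictor_timepoint=tp, penalty=g.penalty, mixing=g.mixing)
        for v in g.variants for o in g.outcomes for h in g.horizons
        for tp in g.predictor_timepoints
    ]
    if not specs:
        raise ValueError("empty model grid")
    return specs


@dataclass
class ModelResult:
    """Everything retained from one fitted grid cell."""

    spec: ModelSpec
    n_rows: int
    result: BootstrapResult
    threshold: float
    summaries: list[SelectionSummary]
    tested_features: list[str]
    provenance: dict
    master_seed: int


@dataclass
class PipelineRun:
    config: PipelineConfig
    seed: int
    results: list[ModelResult] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def exit_code(self) -> int:
        if not self.results:
            return 2
        return 1 if self.failures else 0


def _model_seed(seed: int, index: int) -> int:
    state = np.random.SeedSequence([seed, 1000 + index]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def fit_model(frame: pd.DataFrame, spec: ModelSpec, config: PipelineConfig,
              master_seed: int) -> ModelResult:
    """Assemble -> filter -> impute -> standardize -> bootstrap -> summarize."""
    table = assemble_table(frame, spec)
    threshold = config.missing_thresholds.get(
        spec.variant, 0.30 if spec.variant == "all_data" else 1.0)
    table = preprocess(table, threshold)
    result = bootstrap_select(table, spec, master_seed,
                              stratify=config.stratify_bootstrap,
                              n_folds=config.cv_folds,
                              lambda_rule=config.lambda_rule)
    thr = selection_threshold(result.selection_counts)
    summaries = summarize_selected(result)
    tested = [c for c in table.X.columns if c not in table.forced]
    prov = dict(table.provenance)
    prov["retrodictive"] = spec.retrodictive
    prov["unstable"] = result.unstable
    return ModelResult(spec=spec, n_rows=table.n_rows, result=result,
                       threshold=thr, summaries=summaries,
                       tested_features=tested, provenance=prov,
                       master_seed=master_seed)


def load_cohort(config: PipelineConfig) -> pd.DataFrame:
    if config.cohort_path is not None:
        return read_cohort_csv(config.cohort_path)
    if config.sim is not None:
        return generate_frame(config.sim)
    return generate_frame(SimConfig(seed=config.seed))


def run_pipeline(config: PipelineConfig, outdir=None,
                 frame: Optional[pd.DataFrame] = None) -> PipelineRun:
    """Run every grid cell on the cohort and (optionally) write all artifacts."""
    if frame is None:
        frame = load_cohort(config)
    specs = enumerate_model_grid(config)
    run = PipelineRun(config=config, seed=config.seed)
    for i, spec in enumerate(specs):
        seed_i = _model_seed(config.seed, i)
        try:
            mr = fit_model(frame, spec, config, seed_i)
        except EmptyTableError as exc:
            log.warning("model %s skipped: %s", spec.label(), exc)
            run.failures[spec.label()] = str(exc)
            continue
        log.info("model %s: n=%d B=%d threshold=%.2f selected=%d%s",
                 spec.label(), mr.n_rows, mr.result.n_replicates, mr.threshold,
                 len(mr.summaries), " [retrodictive]" if spec.retrodictive else "")
        run.results.append(mr)
    if outdir is not None:
        write_run_artifacts(run, frame, Path(outdir))
    return run


# ---------------------------------------------------------------------------
# Reporting


def table2_frame(results: list[ModelResult]) -> pd.DataFrame:
    """Table-2-style listing of every retained feature-outcome association."""
    rows = []
    for mr in results:
        for s in mr.summaries:
            rows.append({
                "variant": mr.spec.variant,
                "outcome": mr.spec.outcome,
                "horizon": mr.spec.outcome_horizon,
                "predictor_timepoint": mr.spec.predictor_timepoint,
                "feature": s.feature,
                "coefficient": round(s.mean_coefficient, 6),
                "ci_low": round(s.ci_low, 6),
                "ci_high": round(s.ci_high, 6),
                "selected": s.selected_count,
                "tested": s.n_replicates,
                "n_rows": mr.n_rows,
                "retrodictive": mr.spec.retrodictive,
            })
    cols = ["variant", "outcome", "horizon", "predictor_timepoint", "feature",
            "coefficient", "ci_low", "ci_high", "selected", "tested",
            "n_rows", "retrodictive"]
    return pd.DataFrame(rows, columns=cols)


def model_result_to_dict(mr: ModelResult) -> dict:
    return {
        "spec": dataclasses.asdict(mr.spec),
        "n_rows": mr.n_rows,
        "n_replicates": mr.result.n_replicates,
        "n_discarded": mr.result.n_discarded,
        "master_seed": mr.master_seed,
        "selection_counts": mr.result.selection_counts,
        "threshold": mr.threshold,
        "summaries": [dataclasses.asdict(s) for s in mr.summaries],
        "tested_features": mr.tested_features,
        "forced_coefficient_means": {
            k: (float(np.mean(v)) if v else None)
            for k, v in mr.result.forced_coefficients.items()},
        "provenance": mr.provenance,
    }


def model_result_entries(path: Path) -> list[tuple[ModelSpec, list[SelectionSummary], list[str]]]:
    """Load (spec, summaries, tested) triples from a run's model JSON files."""
    entries = []
    for f in sorted(Path(path).glob("models/*.json")):
        d = json.loads(f.read_text())
        spec = ModelSpec(**d["spec"])
        summaries = [SelectionSummary(**s) for s in d["summaries"]]
        entries.append((spec, summaries, d["tested_features"]))
    return entries


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_run_artifacts(run: PipelineRun, frame: pd.DataFrame, outdir: Path) -> None:
    outdir = Path(outdir)
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    (outdir / "networks").mkdir(exist_ok=True)

    table2_frame(run.results).to_csv(outdir / "table2.csv", index=False)
    for i, mr in enumerate(run.results):
        name = mr.spec.label().replace(":", "_").replace("~", "_").replace("@", "_")
        with open(outdir / "models" / f"{i:02d}_{name}.json", "w") as fh:
            json.dump(model_result_to_dict(mr), fh, indent=1, sort_keys=True)
    entries = [(mr.spec, mr.summaries, mr.tested_features) for mr in run.results]
    for stratum in FIGURE_STRATA:
        g = build_network(entries, stratum)
        export_network(g, outdir / "networks" / f"{stratum.name}.graphml", "graphml")
        export_network(g, outdir / "networks" / f"{stratum.name}.tsv", "tsv")
    missingness_matrix(frame).to_csv(outdir / "missingness.csv")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump({mr.spec.label(): mr.provenance for mr in run.results},
                  fh, indent=1, sort_keys=True)
    import sklearn
    manifest = {
        "config": run.config.model_dump(mode="json"),
        "config_sha256": _config_hash(run.config),
        "seed": run.seed,
        "n_models_fitted": len(run.results),
        "failures": run.failures,
        "versions": {"sarcnet": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "scikit-learn": sklearn.__version__},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Descriptive biomarker comparison


def biomarker_group_summary(frame: pd.DataFrame, status_timepoint: str = "h48",
                            bio_timepoint: str = "h48") -> pd.DataFrame:
    """Per-biomarker comparison between sarcopenic and non-sarcopenic groups.

    Descriptive only: group means/medians with unpaired t and Wilcoxon
    rank-sum statistics and two-sided p-values, no multiplicity adjustment.
    The rank-sum test uses the normal approximation without continuity
    correction, so identical groups give p = 1 exactly.  A biomarker with
    fewer than two observations in either group is flagged not computable.
    """
    sub = frame[frame["timepoint"] == bio_timepoint]
    status = frame[frame["timepoint"] == status_timepoint].set_index(
        "participant_id")["sarc_status"]
    bio_cols = sorted(c for c in frame.columns if c.startswith(BIO_PREFIX))
    rows = []
    for col in bio_cols:
        merged = pd.DataFrame({
            "value": sub.set_index("participant_id")[col],
            "status": status,
        }).dropna()
        g0 = merged.loc[merged["status"] == 0, "value"].to_numpy(float)
        g1 = merged.loc[merged["status"] == 1, "value"].to_numpy(float)
        row = {"biomarker": col[len(BIO_PREFIX):], "n_no_sarc": len(g0),
               "n_sarc": len(g1)}
        if len(g0) < 2 or len(g1) < 2:
            row.update({"mean_no_sarc": np.nan, "mean_sarc": np.nan,
                        "median_no_sarc": np.nan, "median_sarc": np.nan,
                        "t_stat": np.nan, "t_p": np.nan,
                        "ranksum_stat": np.nan, "ranksum_p": np.nan,
                        "computable": False})
            rows.append(row)
            continue
        row.update({
            "mean_no_sarc": float(g0.mean()), "mean_sarc": float(g1.mean()),
            "median_no_sarc": float(np.median(g0)),
            "median_sarc": float(np.median(g1)),
        })
        if np.all(np.concatenate([g0, g1]) == np.concatenate([g0, g1])[0]):
            # degenerate: every observation identical in both groups
            row.update({"t_stat": 0.0, "t_p": 1.0,
                        "ranksum_stat": len(g0) * len(g1) / 2.0,
                        "ranksum_p": 1.0, "computable": True})
            rows.append(row)
            continue
        t_stat, t_p = stats.ttest_ind(g0, g1)
        u_stat, u_p = stats.mannwhitneyu(g0, g1, alternative="two-sided",
                                         use_continuity=False,
                                         method="asymptotic")
        row.update({"t_stat": float(t_stat), "t_p": float(t_p),
                    "ranksum_stat": float(u_stat), "ranksum_p": float(u_p),
                    "computable": True})
        rows.append(row)
    return pd.DataFrame(rows)
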