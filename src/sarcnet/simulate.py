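"""Synthetic longitudinal cohort generator.

Emulates the structure of an acute-sarcopenia observational study: three
recruitment groups (elective surgery n=24, emergency surgery n=14, medical
n=41 by default), up to four assessment timepoints (preoperative for the
elective group only, 48 hours, 7 days, 13 weeks), mixed-type candidate
predictors (demographics, binary comorbidity and medication flags, muscle
measurements, log-normal systemic biomarkers) and heavy missingness at the
13-week remote follow-up.

Ground-truth structure is planted explicitly so downstream feature selection
can be scored against it:

* continuous muscle outcomes (BATT, echogenicity, Sergi SMM) follow
  participant baselines plus group-specific time deltas plus Gaussian visit
  noise; a planted effect on such an outcome shifts its value at the chosen
  horizon, i.e. enters the change-from-baseline outcome additively;
* sarcopenia status at 7 days / 13 weeks is drawn from a logistic model whose
  linear predictor contains an intercept, the baseline status (classified
  from the generated baseline measurements via the diagnostic cutoffs) and
  the planted log-odds effects;
* features without planted effects are generated i.i.d. and are therefore
  exchangeable null features.

Effect sizes are interpreted per unit for binary features (0/1) and per
log-scale standard deviation for biomarkers.  Everything is deterministic
given ``SimConfig.seed``.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.special import expit

from .cohort import (
    BIO_PREFIX,
    COND_PREFIX,
    DEFAULT_CUTOFFS,
    MED_PREFIX,
    PANEL_FIELDS,
    TIMEPOINTS,
    ParticipantRecord,
    SarcopeniaCutoffs,
    frame_to_cohort,
)

OUTCOME_NAMES = ("SarcAny", "Echo", "BATT", "SMMSergi")
HORIZONS = ("d7", "w13")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


class PlantedEffect(BaseModel):
    """A ground-truth association between one feature and one outcome.

    ``effect`` is on the linear-predictor scale: log-odds for SarcAny,
    outcome units (cm, GSU, kg) for the continuous change outcomes.
    """

    feature: str
    outcome: Literal["SarcAny", "Echo", "BATT", "SMMSergi"]
    horizon: Literal["d7", "w13"] = "d7"
    effect: float

    @field_validator("effect")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not np.isfinite(v):
            raise ValueError("effect size must be finite")
        return v


def _default_conditions() -> dict[str, float]:
    return {
        "COPD": 0.22, "asthma": 0.12, "IHD": 0.25, "diabetes": 0.28,
        "anxiety_depression": 0.20, "cancer": 0.18, "stroke": 0.10,
        "hypertension": 0.55, "CKD": 0.15, "delirium": 0.18,
    }


def _default_medications() -> dict[str, float]:
    return {"steroids": 0.15, "metformin": 0.18, "statin": 0.45,
            "digoxin": 0.06, "diuretic": 0.30}


def _default_biomarkers() -> dict[str, tuple[float, float]]:
    # (mean, sd) of log concentration; units are assay-native (pg/mL etc.)
    return {
        "IL6": (1.6, 0.8), "IL7": (2.0, 0.5), "IL1b": (-0.5, 0.7),
        "IL15": (1.0, 0.5), "TNFa": (2.2, 0.4), "CRP": (3.0, 1.0),
        "GH": (0.0, 0.8), "resistin": (2.3, 0.4), "creatinine": (4.4, 0.3),
        "eGFR": (4.1, 0.3), "WCC": (2.2, 0.3), "neutrophils": (1.9, 0.35),
        "lymphocytes": (0.4, 0.4), "Hb": (4.8, 0.12),
    }


def _default_planted() -> list[PlantedEffect]:
    # Emulates the study's headline association pattern: steroid prescription
    # and COPD raising the odds of sarcopenia at 7 days, delirium lowering
    # thigh thickness and COPD worsening (raising) echogenicity.
    return [
        PlantedEffect(feature="cond_COPD", outcome="SarcAny", horizon="d7", effect=1.3),
        PlantedEffect(feature="med_steroids", outcome="SarcAny", horizon="d7", effect=1.5),
        PlantedEffect(feature="cond_delirium", outcome="BATT", horizon="d7", effect=-0.6),
        PlantedEffect(feature="cond_COPD", outcome="Echo", horizon="d7", effect=6.0),
    ]


class SimConfig(BaseModel):
    """Complete description of one synthetic cohort draw."""

    seed: int = 0
    group_sizes: dict[str, int] = Field(
        default_factory=lambda: {"elective": 24, "emergency": 14, "medical": 41}
    )
    female_fraction: float = 0.392
    age_mean: float = 79.1
    age_sd: float = 6.6
    age_floor: float = 70.0
    ethnicity_probs: dict[str, float] = Field(
        default_factory=lambda: {"White British": 0.937, "White Irish": 0.025,
                                 "Indian": 0.025, "Arab": 0.013}
    )
    smoking_probs: dict[str, float] = Field(
        default_factory=lambda: {"current": 0.12, "ex": 0.45, "never": 0.43}
    )
    conditions: dict[str, float] = Field(default_factory=_default_conditions)
    medications: dict[str, float] = Field(default_factory=_default_medications)
    biomarkers: dict[str, tuple[float, float]] = Field(default_factory=_default_biomarkers)
    planted_effects: list[PlantedEffect] = Field(default_factory=_default_planted)
    #: Logistic model for planted sarcopenia status at 7 d / 13 w.
    sarc_intercept: float = -1.0
    sarc_baseline_coef: float = 2.0
    #: Fraction of participants with systemic biomarker data at 48 h.
    bio_coverage_h48: float = 0.646
    #: Apply the study's assessment schedule (SPPB/gait/PROMIS/biomarkers not
    #: collected at every visit).  Disable for fully complete data.
    assessment_schedule: bool = True
    #: Per-timepoint probability that a participant attends the visit.
    retention: dict[str, float] = Field(
        default_factory=lambda: {"preop": 1.0, "h48": 1.0, "d7": 0.92, "w13": 0.75}
    )
    #: Per-timepoint MCAR cell-missingness rate for measurement/biomarker
    #: columns, mimicking heavier loss at the remote 13-week visit.
    missing_rates: dict[str, float] = Field(
        default_factory=lambda: {"preop": 0.02, "h48": 0.03, "d7": 0.08, "w13": 0.45}
    )
    #: Optional per-feature overrides: column name -> timepoint -> rate.
    missing_overrides: dict[str, dict[str, float]] = Field(default_factory=dict)
    #: Columns lost jointly when an assessment is not done (one ultrasound
    #: session yields all four thicknesses; one BIA reading yields all three
    #: impedance values).  Each block shares a single per-row missingness
    #: draw; other eligible columns are masked cell-by-cell.
    missing_blocks: list[list[str]] = Field(
        default_factory=lambda: [
            ["rf_right_cm", "vi_right_cm", "rf_left_cm", "vi_left_cm"],
            ["resistance_ohm", "reactance_ohm", "phase_angle_deg"],
        ])

    @field_validator("group_sizes")
    @classmethod
    def _sizes(cls, v: dict[str, int]) -> dict[str, int]:
        for g, n in v.items():
            if g not in ("elective", "emergency", "medical"):
                raise ValueError(f"unknown group {g!r}")
            if n < 1:
                raise ValueError(f"group size for {g!r} must be >= 1")
        return v

    @field_validator("retention", "missing_rates")
    @classmethod
    def _rates(cls, v: dict[str, float]) -> dict[str, float]:
        for tp, r in v.items():
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate for {tp!r} must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_planted(self) -> "SimConfig":
        known = {"age", "sex_male"}
        known |= {COND_PREFIX + k for k in self.conditions}
        known |= {MED_PREFIX + k for k in self.medications}
        known |= {BIO_PREFIX + k for k in self.biomarkers}
        for pe in self.planted_effects:
            if pe.feature not in known:
                raise ConfigurationError(
                    f"planted effect on unknown feature {pe.feature!r}"
                )
        for name in ("female_fraction", "bio_coverage_h48"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        return self


# group -> timepoint -> (handgrip, BATT, echogenicity, SMM) latent deltas
# from each participant's own baseline, in kg / cm / GSU / kg.
_GROUP_DELTAS = {
    "elective": {"preop": (0.0, 0.0, 0.0, 0.0), "h48": (-2.0, -0.30, 3.0, -0.8),
                 "d7": (-1.5, -0.25, 4.0, -0.7), "w13": (-0.3, -0.05, 1.0, -0.2)},
    "emergency": {"h48": (0.0, 0.0, 0.0, 0.0), "d7": (-2.5, -0.45, 5.0, -1.0),
                  "w13": (-0.8, -0.15, 2.0, -0.4)},
    "medical": {"h48": (0.0, 0.0, 0.0, 0.0), "d7": (-1.8, -0.35, 4.5, -0.9),
                "w13": (-0.5, -0.10, 1.5, -0.3)},
}
# visit-to-visit measurement noise SDs for (handgrip, BATT, echo, SMM)
_VISIT_SD = (2.0, 0.25, 4.0, 0.7)

# per-sex latent baseline (mean, sd): chosen so a realistic minority of an
# over-70 acute cohort sits below the diagnostic cutoffs at baseline
_BASELINES = {
    "handgrip": {"female": (17.0, 5.0), "male": (28.0, 7.0)},
    "batt": {"female": (4.2, 0.8), "male": (5.8, 1.0)},
    "echo": {"female": (74.0, 14.0), "male": (70.0, 14.0)},
    "smm": {"female": (16.5, 2.5), "male": (22.0, 3.0)},
    "height": {"female": (158.0, 6.0), "male": (172.0, 7.0)},
    "weight": {"female": (68.0, 13.0), "male": (80.0, 14.0)},
}

_SERGI = {"c0": -3.964, "ht2r": 0.227, "wt": 0.095, "male": 1.384, "xc": 0.064}


def _feature_value(config: SimConfig, name: str, columns: dict[str, np.ndarray]) -> np.ndarray:
    """Covariate vector a planted effect multiplies (binary raw, biomarker z)."""
    if name.startswith(BIO_PREFIX):
        mu, sd = config.biomarkers[name[len(BIO_PREFIX):]]
        with np.errstate(divide="ignore"):
            logv = np.log(columns[name])
        return (logv - mu) / sd
    if name == "age":
        return (columns["age"] - config.age_mean) / config.age_sd
    return columns[name].astype(float)


def generate_frame(config: SimConfig) -> pd.DataFrame:
    """Draw one cohort as a tidy frame (one row per participant-visit)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    groups, sizes = zip(*sorted(config.group_sizes.items()))
    n = int(sum(sizes))
    group = np.repeat(groups, sizes)

    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    male = (sex == "male").astype(float)
    # truncated normal by resampling below the floor
    age = rng.normal(config.age_mean, config.age_sd, n)
    while (age < config.age_floor).any():
        bad = age < config.age_floor
        age[bad] = rng.normal(config.age_mean, config.age_sd, int(bad.sum()))
    eth_levels = list(config.ethnicity_probs)
    eth_p = np.array([config.ethnicity_probs[k] for k in eth_levels], dtype=float)
    ethnicity = rng.choice(eth_levels, n, p=eth_p / eth_p.sum())
    smoke_levels = list(config.smoking_probs)
    smoke_p = np.array([config.smoking_probs[k] for k in smoke_levels], dtype=float)
    smoking = rng.choice(smoke_levels, n, p=smoke_p / smoke_p.sum())

    flags: dict[str, np.ndarray] = {}
    for name, prev in config.conditions.items():
        flags[COND_PREFIX + name] = (rng.random(n) < prev).astype(int)
    for name, prev in config.medications.items():
        flags[MED_PREFIX + name] = (rng.random(n) < prev).astype(int)

    def draw(base_key: str) -> np.ndarray:
        mu = np.array([_BASELINES[base_key][s][0] for s in sex])
        sd = np.array([_BASELINES[base_key][s][1] for s in sex])
        return rng.normal(mu, sd)

    hgs0 = np.clip(draw("handgrip"), 1.0, None)
    batt0 = np.clip(draw("batt"), 1.0, None)
    echo0 = np.clip(draw("echo"), 20.0, 160.0)
    smm0 = np.clip(draw("smm"), 6.0, None)
    height = draw("height")
    weight = np.clip(draw("weight"), 35.0, None)
    # stable per-participant split of BATT into RF/VI x right/left
    props = rng.dirichlet((30.0, 22.0, 28.0, 20.0), size=n)

    bio_names = list(config.biomarkers)
    has_bio_h48 = rng.random(n) < config.bio_coverage_h48

    # per-timepoint latent values and noise, planted continuous effects
    latent: dict[str, dict[str, np.ndarray]] = {}
    visits: dict[str, np.ndarray] = {}
    base0 = {"handgrip": hgs0, "batt": batt0, "echo": echo0, "smm": smm0}
    col_lookup = dict(flags)
    col_lookup["age"] = age
    col_lookup["sex_male"] = male
    planted_cont: dict[tuple[str, str], np.ndarray] = {}
    planted_sarc: dict[str, np.ndarray] = {h: np.zeros(n) for h in HORIZONS}
    for pe in config.planted_effects:
        if pe.feature.startswith(BIO_PREFIX):
            continue  # biomarker effects applied after biomarker draw below
        x = _feature_value(config, pe.feature, col_lookup)
        if pe.outcome == "SarcAny":
            planted_sarc[pe.horizon] += pe.effect * x
        else:
            key = (pe.outcome, pe.horizon)
            planted_cont[key] = planted_cont.get(key, np.zeros(n)) + pe.effect * x

    bio_draws: dict[tuple[str, str], np.ndarray] = {}
    for tp in TIMEPOINTS:
        for bname in bio_names:
            mu, sd = config.biomarkers[bname]
            bio_draws[(tp, bname)] = np.exp(rng.normal(mu, sd, n))
    for pe in config.planted_effects:
        if not pe.feature.startswith(BIO_PREFIX):
            continue
        bname = pe.feature[len(BIO_PREFIX):]
        mu, sd = config.biomarkers[bname]
        z = (np.log(bio_draws[("h48", bname)]) - mu) / sd
        if pe.outcome == "SarcAny":
            planted_sarc[pe.horizon] += pe.effect * z
        else:
            key = (pe.outcome, pe.horizon)
            planted_cont[key] = planted_cont.get(key, np.zeros(n)) + pe.effect * z

    outcome_key = {"BATT": "batt", "Echo": "echo", "SMMSergi": "smm"}
    for tp in TIMEPOINTS:
        vals: dict[str, np.ndarray] = {}
        attends = np.ones(n, dtype=bool)
        for gi, g in enumerate(groups):
            if tp not in _GROUP_DELTAS[g]:
                attends[group == g] = False
        deltas = np.zeros((n, 4))
        for g in groups:
            if tp in _GROUP_DELTAS[g]:
                deltas[group == g] = _GROUP_DELTAS[g][tp]
        noise = rng.normal(0.0, _VISIT_SD, size=(n, 4))
        for j, key in enumerate(("handgrip", "batt", "echo", "smm")):
            v = base0[key] + deltas[:, j] + noise[:, j]
            for (oname, horizon), contrib in planted_cont.items():
                if tp == horizon and outcome_key[oname] == key:
                    v = v + contrib
            vals[key] = v
        vals["handgrip"] = np.clip(vals["handgrip"], 0.0, None)
        vals["batt"] = np.clip(vals["batt"], 0.2, None)
        vals["echo"] = np.clip(vals["echo"], 5.0, 255.0)
        vals["smm"] = np.clip(vals["smm"], 4.0, None)
        latent[tp] = vals
        visits[tp] = attends

    # baseline status classified from the baseline visit's generated values
    baseline_tp = np.where(group == "elective", "preop", "h48")
    hgs_b = np.empty(n)
    batt_b = np.empty(n)
    smm_b = np.empty(n)
    for tp in ("preop", "h48"):
        m = baseline_tp == tp
        hgs_b[m] = latent[tp]["handgrip"][m]
        batt_b[m] = latent[tp]["batt"][m]
        smm_b[m] = latent[tp]["smm"][m]
    cut = DEFAULT_CUTOFFS
    hg_cut = np.array([cut.handgrip_low[s] for s in sex])
    batt_cut = np.array([cut.batt_low[s] for s in sex])
    smm_cut = np.array([cut.smm_low[s] for s in sex])
    s0 = ((hgs_b < hg_cut) & ((batt_b < batt_cut) | (smm_b < smm_cut))).astype(int)

    status: dict[str, np.ndarray] = {}
    for tp in ("preop", "h48"):
        status[tp] = ((latent[tp]["handgrip"] < hg_cut)
                      & ((latent[tp]["batt"] < batt_cut)
                         | (latent[tp]["smm"] < smm_cut))).astype(int)
    for tp in HORIZONS:
        lp = config.sarc_intercept + config.sarc_baseline_coef * s0 + planted_sarc[tp]
        status[tp] = (rng.random(n) < expit(lp)).astype(int)

    reactance = rng.normal(48.0, 8.0, n)
    phase = {tp: np.clip(rng.normal(4.6, 0.8, n), 1.5, None) for tp in TIMEPOINTS}
    sppb = {tp: np.clip(np.round(rng.normal(8.0, 2.5, n)), 0, 12) for tp in TIMEPOINTS}
    gait = {tp: np.clip(rng.normal(0.8, 0.25, n), 0.1, None) for tp in TIMEPOINTS}
    promis = {tp: rng.normal(42.0, 8.0, n) for tp in TIMEPOINTS}
    weight_tp = {tp: weight + rng.normal(0.0, 1.0, n) for tp in TIMEPOINTS}

    rows = []
    for tp in TIMEPOINTS:
        attends = visits[tp]
        if not attends.any():
            continue
        vals = latent[tp]
        # back-solve resistance so the Sergi equation reproduces latent SMM
        denom = (vals["smm"] - _SERGI["c0"] - _SERGI["wt"] * weight_tp[tp]
                 - _SERGI["male"] * male - _SERGI["xc"] * reactance)
        denom = np.clip(denom, 1.0, None)
        resistance = _SERGI["ht2r"] * height**2 / denom
        block = {
            "participant_id": np.array([f"P{i + 1:03d}" for i in range(n)]),
            "timepoint": np.full(n, tp, dtype=object),
            "group": group,
            "sex": sex,
            "age": age,
            "ethnicity": ethnicity,
            "smoking": smoking,
        }
        for fname, arr in flags.items():
            block[fname] = arr
        block.update({
            "handgrip_kg": vals["handgrip"],
            "rf_right_cm": vals["batt"] * props[:, 0],
            "vi_right_cm": vals["batt"] * props[:, 1],
            "rf_left_cm": vals["batt"] * props[:, 2],
            "vi_left_cm": vals["batt"] * props[:, 3],
            "echogenicity_gsu": vals["echo"],
            "resistance_ohm": resistance,
            "reactance_ohm": reactance,
            "phase_angle_deg": phase[tp],
            "height_cm": height,
            "weight_kg": weight_tp[tp],
            "sppb_score": sppb[tp],
            "gait_speed_mps": gait[tp],
            "promis_pf_score": promis[tp],
        })
        for bname in bio_names:
            # serum samples are drawn preoperatively (elective) and within
            # 48 h; later visits carry no biomarkers under the schedule
            v = bio_draws[(tp, bname)].copy()
            if config.assessment_schedule:
                if tp == "h48":
                    v[~has_bio_h48] = np.nan
                elif tp != "preop":
                    v[:] = np.nan
            block[BIO_PREFIX + bname] = v
        if config.assessment_schedule:
            block["sppb_score"] = _schedule_mask(block["sppb_score"], group, tp, "sppb")
            block["gait_speed_mps"] = _schedule_mask(block["gait_speed_mps"], group, tp, "gait")
            block["promis_pf_score"] = _schedule_mask(block["promis_pf_score"], group, tp, "promis")
        block["sarc_status"] = status[tp].astype(float)
        sub = pd.DataFrame(block)[attends]
        rows.append(sub)
    frame = pd.concat(rows, ignore_index=True)
    frame["sarc_status"] = frame["sarc_status"].astype("Float64")
    frame = apply_missingness(frame, config)

    # visit dropout (baseline visits always kept)
    drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    keep = np.ones(len(frame), dtype=bool)
    is_baseline = np.where(frame["group"] == "elective", "preop", "h48")
    for tp in TIMEPOINTS:
        r = config.retention.get(tp, 1.0)
        m = (frame["timepoint"] == tp).to_numpy() & (is_baseline != tp)
        if r < 1.0 and m.any():
            keep[m] &= drop_rng.random(int(m.sum())) < r
    frame = frame[keep].reset_index(drop=True)
    order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    frame = frame.sort_values(
        ["participant_id", "timepoint"],
        key=lambda s: s.map(order) if s.name == "timepoint" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return frame


def _schedule_mask(values: np.ndarray, group: np.ndarray, tp: str, what: str) -> np.ndarray:
    """Apply the study's assessment schedule for function scores."""
    out = np.asarray(values, dtype=float).copy()
    if what == "sppb":
        allowed = {"elective": {"preop", "w13"}, "emergency": {"w13"},
                   "medical": {"preop", "h48", "d7", "w13"}}
    elif what == "gait":
        allowed = {"elective": {"d7"}, "emergency": {"d7"},
                   "medical": {"preop", "h48", "d7", "w13"}}
    else:  # patient-reported function at baseline and follow-up
        allowed = {"elective": {"preop", "w13"}, "emergency": {"h48", "w13"},
                   "medical": {"h48", "w13"}}
    mask = ~np.isin(group, [g for g, tps in allowed.items() if tp in tps])
    out[mask] = np.nan
    return out


def apply_missingness(frame: pd.DataFrame, config: SimConfig,
                      rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Set measurement/biomarker cells missing completely at random.

    Each eligible cell is masked independently with its configured
    per-timepoint rate (``missing_rates``, overridable per feature via
    ``missing_overrides``).  Deterministic given ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    frame = frame.copy()
    eligible = [c for c in frame.columns
                if c in PANEL_FIELDS or c.startswith(BIO_PREFIX)]
    extra = [c for c in config.missing_overrides if c not in eligible and c in frame.columns]
    tp_col = frame["timepoint"].to_numpy()
    # assessment blocks: one draw masks the whole instrument reading
    in_block: set[str] = set()
    for block in config.missing_blocks:
        cols = [c for c in block if c in frame.columns]
        if not cols:
            continue
        in_block.update(cols)
        values = {c: frame[c].to_numpy(dtype=float, copy=True) for c in cols}
        for tp in TIMEPOINTS:
            rate = config.missing_overrides.get(cols[0], {}).get(
                tp, config.missing_rates.get(tp, 0.0))
            m = tp_col == tp
            if rate <= 0.0 or not m.any():
                continue
            hit = rng.random(int(m.sum())) < rate
            idx = np.flatnonzero(m)[hit]
            for c in cols:
                values[c][idx] = np.nan
        for c in cols:
            frame[c] = values[c]
    eligible = [c for c in eligible if c not in in_block]
    for col in eligible + extra:
        values = frame[col].to_numpy(dtype=float, copy=True)
        for tp in TIMEPOINTS:
            rate = config.missing_overrides.get(col, {}).get(
                tp, config.missing_rates.get(tp, 0.0) if col not in extra else 0.0)
            m = tp_col == tp
            if rate <= 0.0 or not m.any():
                continue
            hit = rng.random(int(m.sum())) < rate
            idx = np.flatnonzero(m)[hit]
            values[idx] = np.nan
        frame[col] = values
    return frame


def generate_cohort(config: SimConfig) -> list[ParticipantRecord]:
    """Draw one cohort as typed participant records."""
    return frame_to_cohort(generate_frame(config))
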