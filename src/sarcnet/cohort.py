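"""Domain model for the acute-sarcopenia cohort.

A cohort is a longitudinal table of older adults (>= 70 y) recruited around a
stressor event (elective colorectal surgery, emergency abdominal surgery, or
acute medical admission) and assessed at up to four timepoints: preoperative
(elective group only), within 48 hours, at 7 days, and at 13 weeks.  Each
assessment yields muscle strength (handgrip), muscle quantity (ultrasound
thigh thickness, bioimpedance-estimated skeletal muscle mass), muscle quality
(rectus femoris echogenicity) and systemic biomarkers.

This module holds the record types, the deterministic clinical derivations
(BATT, the Sergi and Janssen skeletal-muscle-mass equations, sarcopenia
classification from per-sex cutoffs) and tidy-CSV I/O.  Missing inputs
propagate as ``None``/``NaN`` results rather than exceptions so that sparse
records never abort cohort assembly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd

TIMEPOINTS = ("preop", "h48", "d7", "w13")
TIMEPOINT_ORDER = {tp: i for i, tp in enumerate(TIMEPOINTS)}
GROUPS = ("elective", "emergency", "medical")
SEXES = ("female", "male")
SMOKING_LEVELS = ("current", "ex", "never")

#: Measurement fields carried by every panel (all nullable floats).
PANEL_FIELDS = (
    "handgrip_kg",
    "rf_right_cm",
    "vi_right_cm",
    "rf_left_cm",
    "vi_left_cm",
    "echogenicity_gsu",
    "resistance_ohm",
    "reactance_ohm",
    "phase_angle_deg",
    "height_cm",
    "weight_kg",
    "sppb_score",
    "gait_speed_mps",
    "promis_pf_score",
)

# Skeletal-muscle-mass prediction equations from bioimpedance.  The
# coefficients live here, in one block, so they can be corrected without
# touching any code path.  Sex is encoded male=1 / female=0, the convention
# of the source equations.
SERGI_COEFFS = {
    "intercept": -3.964,
    "ht2_over_r": 0.227,   # height_cm^2 / resistance_ohm
    "weight": 0.095,       # kg
    "male": 1.384,
    "reactance": 0.064,    # ohm
}
JANSSEN_COEFFS = {
    "intercept": 5.102,
    "ht2_over_r": 0.401,
    "male": 3.825,
    "age": -0.071,         # years
}


@dataclass(frozen=True)
class SarcopeniaCutoffs:
    """Per-sex diagnostic cutoffs; a value strictly below its cutoff is low.

    Defaults are the published thresholds: handgrip <16 kg (F) / <27 kg (M),
    BATT <3.85 cm (F) / <5.44 cm (M), SMM <15 kg (F) / <20 kg (M).
    """

    handgrip_low: Mapping[str, float] = field(
        default_factory=lambda: {"female": 16.0, "male": 27.0}
    )
    batt_low: Mapping[str, float] = field(
        default_factory=lambda: {"female": 3.85, "male": 5.44}
    )
    smm_low: Mapping[str, float] = field(
        default_factory=lambda: {"female": 15.0, "male": 20.0}
    )

    def __post_init__(self) -> None:
        for name in ("handgrip_low", "batt_low", "smm_low"):
            table = getattr(self, name)
            for sex in SEXES:
                if sex not in table:
                    raise ValueError(f"{name} missing cutoff for sex {sex!r}")
                if not table[sex] > 0:
                    raise ValueError(f"{name}[{sex!r}] must be > 0")


DEFAULT_CUTOFFS = SarcopeniaCutoffs()


@dataclass
class MeasurementPanel:
    """All measured values at one timepoint; any field may be missing."""

    handgrip_kg: Optional[float] = None
    rf_right_cm: Optional[float] = None
    vi_right_cm: Optional[float] = None
    rf_left_cm: Optional[float] = None
    vi_left_cm: Optional[float] = None
    echogenicity_gsu: Optional[float] = None
    resistance_ohm: Optional[float] = None
    reactance_ohm: Optional[float] = None
    phase_angle_deg: Optional[float] = None
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    sppb_score: Optional[float] = None
    gait_speed_mps: Optional[float] = None
    promis_pf_score: Optional[float] = None
    biomarkers: dict[str, Optional[float]] = field(default_factory=dict)
    #: Sarcopenia status at this timepoint (0/1), either classified from the
    #: measurements or planted by the synthetic generator; None if unknown.
    sarc_status: Optional[int] = None

    def __post_init__(self) -> None:
        nonneg = (
            "rf_right_cm", "vi_right_cm", "rf_left_cm", "vi_left_cm",
            "handgrip_kg", "resistance_ohm", "height_cm", "weight_kg",
        )
        for name in nonneg:
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        e = self.echogenicity_gsu
        if e is not None and not math.isnan(e) and not (0 <= e <= 255):
            raise ValueError(f"echogenicity_gsu must lie in [0, 255], got {e}")
        for k, v in self.biomarkers.items():
            if v is not None and not math.isnan(v) and v < 0:
                raise ValueError(f"biomarker {k!r} must be >= 0, got {v}")


@dataclass
class ParticipantRecord:
    """One study participant with constant attributes and per-timepoint panels."""

    id: str
    group: str
    sex: str
    age: float
    ethnicity: str = "White British"
    smoking: str = "never"
    condition_flags: dict[str, int] = field(default_factory=dict)
    medication_flags: dict[str, int] = field(default_factory=dict)
    panels: dict[str, MeasurementPanel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age < 70:
            raise ValueError(f"age must be >= 70 (study inclusion), got {self.age}")
        if self.smoking not in SMOKING_LEVELS:
            raise ValueError(f"unknown smoking level {self.smoking!r}")
        for flags in (self.condition_flags, self.medication_flags):
            for k, v in flags.items():
                if v not in (0, 1):
                    raise ValueError(f"flag {k!r} must be 0 or 1, got {v}")
        for tp in self.panels:
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r}")
        if self.group != "elective" and "preop" in self.panels:
            raise ValueError(f"{self.group} participants have no preoperative visit")

    @property
    def baseline_timepoint(self) -> Optional[str]:
        """Earliest attended visit: preop for elective, else 48 h."""
        for tp in TIMEPOINTS:
            if tp in self.panels:
                return tp
        return None


# ---------------------------------------------------------------------------
# Clinical derivations


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def compute_batt(rf_right_cm, vi_right_cm, rf_left_cm, vi_left_cm):
    """Bilateral anterior thigh thickness: right RF + right VI + left RF + left VI.

    Returns NaN if any thickness is missing or negative.
    """
    vals = (rf_right_cm, vi_right_cm, rf_left_cm, vi_left_cm)
    if any(_missing(v) or v < 0 for v in vals):
        return float("nan")
    return float(sum(vals))


def estimate_smm_sergi(height_cm, weight_kg, resistance_ohm, reactance_ohm, sex):
    """Skeletal muscle mass (kg) from the Sergi bioimpedance equation.

    SMM = -3.964 + 0.227 * Ht^2/R + 0.095 * Wt + 1.384 * male + 0.064 * Xc.
    Returns NaN on missing input or non-positive resistance.
    """
    if any(_missing(v) for v in (height_cm, weight_kg, resistance_ohm, reactance_ohm)):
        return float("nan")
    if resistance_ohm <= 0:
        return float("nan")
    c = SERGI_COEFFS
    return (
        c["intercept"]
        + c["ht2_over_r"] * height_cm**2 / resistance_ohm
        + c["weight"] * weight_kg
        + c["male"] * (1 if sex == "male" else 0)
        + c["reactance"] * reactance_ohm
    )


def estimate_smm_janssen(height_cm, resistance_ohm, sex, age_years):
    """Skeletal muscle mass (kg) from the Janssen bioimpedance equation.

    SM = 0.401 * Ht^2/R + 3.825 * male - 0.071 * age + 5.102.
    Returns NaN on missing input or non-positive resistance.
    """
    if any(_missing(v) for v in (height_cm, resistance_ohm, age_years)):
        return float("nan")
    if resistance_ohm <= 0:
        return float("nan")
    c = JANSSEN_COEFFS
    return (
        c["intercept"]
        + c["ht2_over_r"] * height_cm**2 / resistance_ohm
        + c["male"] * (1 if sex == "male" else 0)
        + c["age"] * age_years
    )


PRESENT, ABSENT, INDETERMINATE = "present", "absent", "indeterminate"


def classify_sarcopenia(handgrip_kg, batt_cm, smm_kg, sex,
                        cutoffs: SarcopeniaCutoffs = DEFAULT_CUTOFFS) -> str:
    """Classify sarcopenia: low strength AND (low BATT and/or low SMM).

    Comparisons are strict: a value exactly at its cutoff is NOT low.  Missing
    values are resolved only when the remaining measurements determine the
    outcome; otherwise the result is ``indeterminate``.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    if _missing(handgrip_kg):
        return INDETERMINATE
    if handgrip_kg >= cutoffs.handgrip_low[sex]:
        return ABSENT  # non-low strength decides regardless of quantity
    batt_low = None if _missing(batt_cm) else batt_cm < cutoffs.batt_low[sex]
    smm_low = None if _missing(smm_kg) else smm_kg < cutoffs.smm_low[sex]
    if batt_low or smm_low:  # any observed low quantity confirms
        return PRESENT
    if batt_low is False and smm_low is False:
        return ABSENT
    # strength low, but a missing quantity measure could still flip the call
    return INDETERMINATE


def panel_sarcopenia_status(panel: MeasurementPanel, sex: str,
                            cutoffs: SarcopeniaCutoffs = DEFAULT_CUTOFFS) -> str:
    """Classify one panel, deriving BATT and Sergi SMM from its raw fields."""
    batt = compute_batt(panel.rf_right_cm, panel.vi_right_cm,
                        panel.rf_left_cm, panel.vi_left_cm)
    smm = estimate_smm_sergi(panel.height_cm, panel.weight_kg,
                             panel.resistance_ohm, panel.reactance_ohm, sex)
    return classify_sarcopenia(panel.handgrip_kg, batt, smm, sex, cutoffs)


# ---------------------------------------------------------------------------
# Tidy-frame representation and CSV I/O

CONSTANT_COLUMNS = ("participant_id", "timepoint", "group", "sex", "age",
                    "ethnicity", "smoking")
COND_PREFIX = "cond_"
MED_PREFIX = "med_"
BIO_PREFIX = "bio_"


def cohort_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Tidy frame: one row per (participant, timepoint); missing cells NaN."""
    rows = []
    for rec in records:
        for tp in TIMEPOINTS:
            if tp not in rec.panels:
                continue
            panel = rec.panels[tp]
            row: dict = {
                "participant_id": rec.id,
                "timepoint": tp,
                "group": rec.group,
                "sex": rec.sex,
                "age": rec.age,
                "ethnicity": rec.ethnicity,
                "smoking": rec.smoking,
            }
            for k, v in rec.condition_flags.items():
                row[COND_PREFIX + k] = v
            for k, v in rec.medication_flags.items():
                row[MED_PREFIX + k] = v
            for name in PANEL_FIELDS:
                row[name] = getattr(panel, name)
            for k, v in panel.biomarkers.items():
                row[BIO_PREFIX + k] = v
            row["sarc_status"] = panel.sarc_status
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame["sarc_status"] = frame["sarc_status"].astype("Float64")
    return frame


def frame_to_cohort(frame: pd.DataFrame) -> list[ParticipantRecord]:
    """Inverse of :func:`cohort_to_frame`."""
    records = []
    for pid, sub in frame.groupby("participant_id", sort=False):
        first = sub.iloc[0]
        cond = {c[len(COND_PREFIX):]: int(first[c]) for c in sub.columns
                if c.startswith(COND_PREFIX) and not pd.isna(first[c])}
        med = {c[len(MED_PREFIX):]: int(first[c]) for c in sub.columns
               if c.startswith(MED_PREFIX) and not pd.isna(first[c])}
        panels = {}
        for _, row in sub.iterrows():
            bio = {c[len(BIO_PREFIX):]: (None if pd.isna(row[c]) else float(row[c]))
                   for c in sub.columns if c.startswith(BIO_PREFIX)}
            kwargs = {name: (None if pd.isna(row[name]) else float(row[name]))
                      for name in PANEL_FIELDS if name in row}
            status = row.get("sarc_status")
            panels[row["timepoint"]] = MeasurementPanel(
                biomarkers=bio,
                sarc_status=None if pd.isna(status) else int(status),
                **kwargs,
            )
        records.append(ParticipantRecord(
            id=str(pid), group=first["group"], sex=first["sex"],
            age=float(first["age"]), ethnicity=first["ethnicity"],
            smoking=first["smoking"], condition_flags=cond,
            medication_flags=med, panels=panels,
        ))
    return records


def add_derived_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Append batt_cm, smm_sergi_kg and smm_janssen_kg columns to a tidy frame."""
    out = frame.copy()
    out["batt_cm"] = [
        compute_batt(r, v, rl, vl)
        for r, v, rl, vl in zip(frame["rf_right_cm"], frame["vi_right_cm"],
                                frame["rf_left_cm"], frame["vi_left_cm"])
    ]
    out["smm_sergi_kg"] = [
        estimate_smm_sergi(h, w, res, rea, sex)
        for h, w, res, rea, sex in zip(frame["height_cm"], frame["weight_kg"],
                                       frame["resistance_ohm"],
                                       frame["reactance_ohm"], frame["sex"])
    ]
    out["smm_janssen_kg"] = [
        estimate_smm_janssen(h, res, sex, age)
        for h, res, sex, age in zip(frame["height_cm"], frame["resistance_ohm"],
                                    frame["sex"], frame["age"])
    ]
    return out


def fill_sarcopenia_status(frame: pd.DataFrame,
                           cutoffs: SarcopeniaCutoffs = DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Fill missing sarc_status cells by classifying each row's measurements.

    Indeterminate classifications stay missing.
    """
    out = add_derived_columns(frame)
    status = []
    for _, row in out.iterrows():
        if "sarc_status" in row and not pd.isna(row["sarc_status"]):
            status.append(float(row["sarc_status"]))
            continue
        call = classify_sarcopenia(row["handgrip_kg"], row["batt_cm"],
                                   row["smm_sergi_kg"], row["sex"], cutoffs)
        status.append({PRESENT: 1.0, ABSENT: 0.0}.get(call, float("nan")))
    frame = frame.copy()
    frame["sarc_status"] = pd.array(status, dtype="Float64")
    return frame


def column_schema(frame: pd.DataFrame) -> dict:
    """Column dictionary for a tidy cohort CSV, serializable as JSON."""
    schema: dict = {"columns": {}}
    for col in frame.columns:
        if col in ("participant_id", "timepoint", "group", "sex", "ethnicity", "smoking"):
            kind = "categorical"
        elif col.startswith((COND_PREFIX, MED_PREFIX)) or col == "sarc_status":
            kind = "binary"
        else:
            kind = "numeric"
        schema["columns"][col] = {"kind": kind}
    schema["timepoints"] = list(TIMEPOINTS)
    schema["groups"] = list(GROUPS)
    return schema


def write_cohort_csv(frame: pd.DataFrame, path, with_schema: bool = True) -> None:
    """Write a tidy cohort CSV (missing cells empty) plus a JSON column schema."""
    frame.to_csv(path, index=False)
    if with_schema:
        schema_path = str(path) + ".schema.json"
        with open(schema_path, "w") as fh:
            json.dump(column_schema(frame), fh, indent=2, sort_keys=True)


def read_cohort_csv(path, compute_status: bool = True) -> pd.DataFrame:
    """Read a tidy cohort CSV; optionally classify any missing sarc_status."""
    frame = pd.read_csv(path)
    bad = set(frame["timepoint"].unique()) - set(TIMEPOINTS)
    if bad:
        raise ValueError(f"unknown timepoints in cohort file: {sorted(bad)}")
    if "sarc_status" not in frame.columns:
        frame["sarc_status"] = pd.array([float("nan")] * len(frame), dtype="Float64")
    else:
        frame["sarc_status"] = frame["sarc_status"].astype("Float64")
    if compute_status:
        frame = fill_sarcopenia_status(frame)
    return frame
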