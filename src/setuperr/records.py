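"""Data model and I/O for 6-DOF patient setup-error logs.

A setup-error log holds one record per image-guidance event: who was imaged
(patient), when (fraction, treatment week), at which point of the workflow
(before couch correction, after correction, after beam delivery, or by
orthogonal planar imaging), and the measured rigid-body error itself —
three translations in millimetres and three rotations in degrees.

Translations are stored in mm and rotations in degrees throughout the
public API, matching couch and imaging-console readouts; trigonometric
code converts to radians internally.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sanity bound on rotation magnitudes (degrees).  Clinical residual
#: rotations are well under 5 degrees; anything near a quarter turn is a
#: data-entry or unit error, not a setup error.
MAX_ROTATION_DEG = 45.0

CSV_COLUMNS = [
    "patient_id",
    "timepoint",
    "fraction",
    "week",
    "anesthesia",
    "x_mm",
    "y_mm",
    "z_mm",
    "yaw_deg",
    "roll_deg",
    "pitch_deg",
    "special_condition",
]

DOF_NAMES = ("x", "y", "z", "yaw", "roll", "pitch")
TRANSLATION_DOFS = ("x", "y", "z")
ROTATION_DOFS = ("yaw", "roll", "pitch")


class Timepoint(str, enum.Enum):
    """Workflow stage at which a setup error was measured."""

    PRECORRECTION = "precorrection"
    POSTCORRECTION = "postcorrection"
    POSTTREATMENT = "posttreatment"
    ORTHOGONAL2D = "orthogonal2D"


class Anesthesia(str, enum.Enum):
    AWAKE = "awake"
    ANESTHETIZED = "anesthetized"
    SEDATED = "sedated"


class ExclusionReason(str, enum.Enum):
    """Why an enrolled patient was removed before analysis."""

    UNCOOPERATIVE = "uncooperative"
    OVER_AGE = "over_age"
    SPINE_ONLY = "spine_only"
    DOWNTIME_OR_CAPTURE_ERROR_OR_DISCRETION = (
        "downtime_or_capture_error_or_discretion"
    )


class SchemaError(ValueError):
    """The CSV is missing required columns or has an unusable layout."""


class ValidationError(ValueError):
    """One or more rows violate a data invariant.

    ``errors`` holds ``(row_index, message)`` diagnostics so callers can
    report every offending row, not just the first.
    """

    def __init__(self, errors: Sequence[tuple[int | None, str]]):
        self.errors = list(errors)
        lines = [
            f"row {i}: {msg}" if i is not None else msg for i, msg in self.errors
        ]
        super().__init__("invalid setup-error data:\n  " + "\n  ".join(lines))


@dataclass(frozen=True)
class SetupError6D:
    """One measured rigid-body correction or residual.

    Parameters
    ----------
    x, y, z : float
        Lateral, longitudinal and vertical translations in mm.
    yaw, roll, pitch : float
        Rotations in degrees.
    """

    x: float
    y: float
    z: float
    yaw: float
    roll: float
    pitch: float

    def __post_init__(self) -> None:
        for name in DOF_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        for name in ROTATION_DOFS:
            v = getattr(self, name)
            if abs(v) >= MAX_ROTATION_DEG:
                raise ValueError(
                    f"|{name}| = {abs(v)} deg exceeds the {MAX_ROTATION_DEG} deg "
                    "sanity bound"
                )

    @property
    def translation(self) -> np.ndarray:
        """Translational part (x, y, z) in mm."""
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def rotation_deg(self) -> np.ndarray:
        """Rotational part (yaw, roll, pitch) in degrees."""
        return np.array([self.yaw, self.roll, self.pitch], dtype=float)

    def as_array(self) -> np.ndarray:
        """Six-vector (x, y, z, yaw, roll, pitch), mm and degrees."""
        return np.array(
            [self.x, self.y, self.z, self.yaw, self.roll, self.pitch], dtype=float
        )


@dataclass(frozen=True)
class ScanRecord:
    """A :class:`SetupError6D` with its identity and workflow metadata."""

    patient_id: str
    timepoint: Timepoint
    fraction: int
    week: int
    anesthesia: Anesthesia
    error: SetupError6D
    special_condition: str | None = None

    def __post_init__(self) -> None:
        if self.fraction < 1:
            raise ValueError(f"fraction must be >= 1, got {self.fraction}")
        if self.week < 1:
            raise ValueError(f"week must be >= 1, got {self.week}")


def week_from_fraction(fraction: int, fractions_per_week: int = 5) -> int:
    """Treatment week implied by a fraction number (1-based)."""
    if fractions_per_week < 1:
        raise ValueError("fractions_per_week must be >= 1")
    return -(-fraction // fractions_per_week)


@dataclass
class Cohort:
    """A validated, ordered collection of scan records.

    Invariants (checked by :meth:`validate`):

    * (patient_id, timepoint, fraction) triples are unique;
    * each patient has at most one post-correction record (the study
      design repeats the volumetric scan once per course).
    """

    records: list[ScanRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self) -> "Cohort":
        errors: list[tuple[int | None, str]] = []
        seen: set[tuple[str, str, int]] = set()
        post_seen: set[str] = set()
        for i, rec in enumerate(self.records):
            key = (rec.patient_id, rec.timepoint.value, rec.fraction)
            if key in seen:
                errors.append((i, f"duplicate record {key}"))
            seen.add(key)
            if rec.timepoint is Timepoint.POSTCORRECTION:
                if rec.patient_id in post_seen:
                    errors.append(
                        (i, f"patient {rec.patient_id} has more than one "
                            "postcorrection record")
                    )
                post_seen.add(rec.patient_id)
        if errors:
            raise ValidationError(errors)
        return self

    def select(
        self,
        timepoint: Timepoint | str | None = None,
        anesthesia: Anesthesia | str | None = None,
    ) -> "Cohort":
        """Sub-cohort restricted to one timepoint and/or anesthesia status."""
        recs = self.records
        if timepoint is not None:
            tp = Timepoint(timepoint)
            recs = [r for r in recs if r.timepoint is tp]
        if anesthesia is not None:
            an = Anesthesia(anesthesia)
            recs = [r for r in recs if r.anesthesia is an]
        return Cohort(records=list(recs), provenance=self.provenance)

    def drop_special_conditions(self, substrings: Iterable[str]) -> "Cohort":
        """Drop records whose special-condition text contains any substring.

        The study protocol documents special conditions (e.g. an uncooperative
        patient or an ill-fitting mask) without prescribing how to handle them
        numerically; this predicate lets users exclude flagged fractions.
        Matching is case-insensitive.
        """
        subs = [s.lower() for s in substrings]
        kept = [
            r
            for r in self.records
            if not (
                r.special_condition
                and any(s in r.special_condition.lower() for s in subs)
            )
        ]
        return Cohort(records=kept, provenance=self.provenance)

    def patient_ids(self) -> list[str]:
        """Unique patient identifiers, in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def dof_matrix(self) -> np.ndarray:
        """(n_records, 6) array of errors: x, y, z (mm), yaw, roll, pitch (deg)."""
        if not self.records:
            return np.empty((0, 6), dtype=float)
        return np.vstack([r.error.as_array() for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "timepoint": r.timepoint.value,
                    "fraction": r.fraction,
                    "week": r.week,
                    "anesthesia": r.anesthesia.value,
                    "x_mm": r.error.x,
                    "y_mm": r.error.y,
                    "z_mm": r.error.z,
                    "yaw_deg": r.error.yaw,
                    "roll_deg": r.error.roll,
                    "pitch_deg": r.error.pitch,
                    "special_condition": r.special_condition or "",
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


@dataclass(frozen=True)
class RosterEntry:
    patient_id: str
    enrolled: bool = True
    exclusion_reason: ExclusionReason | None = None


@dataclass
class EnrollmentRoster:
    """Per-patient enrollment rows with optional exclusion reasons."""

    entries: list[RosterEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self) -> "EnrollmentRoster":
        # excluded implies reason present is enforced by construction: an
        # entry is "excluded" exactly when exclusion_reason is not None.
        ids = [e.patient_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError([(None, "duplicate patient_id in roster")])
        return self

    @property
    def n_enrolled(self) -> int:
        return sum(1 for e in self.entries if e.enrolled)

    @property
    def n_excluded(self) -> int:
        return sum(
            1 for e in self.entries if e.enrolled and e.exclusion_reason is not None
        )


def apply_exclusions(roster: EnrollmentRoster) -> tuple[int, EnrollmentRoster]:
    """Filter an enrollment roster down to the analyzed patients.

    Returns ``(n_analyzed, filtered_roster)`` where the filtered roster
    keeps the enrolled patients without an exclusion reason, and
    ``n_analyzed == n_enrolled - n_excluded`` always holds.
    """
    roster.validate()
    kept = [
        e
        for e in roster.entries
        if e.enrolled and e.exclusion_reason is None
    ]
    return len(kept), EnrollmentRoster(entries=kept)


def imaging_dose_summary(
    ctdi_per_scan: float, n_daily: int, n_extra: int
) -> int:
    """Total course imaging dose in mGy, rounded to the nearest integer.

    ``ctdi_per_scan`` is the per-scan CTDIvol in mGy; ``n_daily`` the number
    of daily guidance scans over the course and ``n_extra`` any additional
    research scans.  Dose adds linearly: total = CTDIvol x (n_daily + n_extra).
    """
    if ctdi_per_scan < 0 or n_daily < 0 or n_extra < 0:
        raise ValueError("imaging dose inputs must be nonnegative")
    total = ctdi_per_scan * (n_daily + n_extra)
    # round half away from zero so e.g. x.5 mGy never rounds down
    return int(math.floor(total + 0.5))


# ---------------------------------------------------------------------------
# CSV I/O


def _coerce_row(
    row: pd.Series, idx: int, fractions_per_week: int
) -> ScanRecord | tuple[int, str]:
    try:
        tp = Timepoint(str(row["timepoint"]))
    except ValueError:
        return (idx, f"unknown timepoint {row['timepoint']!r}")
    try:
        an = Anesthesia(str(row["anesthesia"]))
    except ValueError:
        return (idx, f"unknown anesthesia status {row['anesthesia']!r}")
    vals = {}
    for col, name in zip(
        ["x_mm", "y_mm", "z_mm", "yaw_deg", "roll_deg", "pitch_deg"], DOF_NAMES
    ):
        v = row[col]
        try:
            vals[name] = float(v)
        except (TypeError, ValueError):
            return (idx, f"non-numeric {col}: {v!r}")
    try:
        err = SetupError6D(**vals)
    except ValueError as e:
        return (idx, str(e))

    try:
        fraction = int(row["fraction"])
    except (TypeError, ValueError):
        return (idx, f"non-integer fraction: {row['fraction']!r}")
    week_raw = row.get("week")
    derived = week_from_fraction(fraction, fractions_per_week)
    if week_raw is None or (isinstance(week_raw, float) and math.isnan(week_raw)) \
            or str(week_raw).strip() == "":
        week = derived
    else:
        try:
            week = int(week_raw)
        except (TypeError, ValueError):
            return (idx, f"non-integer week: {week_raw!r}")
        if week != derived:
            # explicit column wins, but the mismatch is worth a warning
            logger.warning(
                "row %d: week %d inconsistent with fraction %d at %d "
                "fractions/week (expected %d); keeping explicit value",
                idx, week, fraction, fractions_per_week, derived,
            )
    special = row.get("special_condition")
    if special is None or (isinstance(special, float) and math.isnan(special)):
        special = None
    else:
        special = str(special) or None
    try:
        return ScanRecord(
            patient_id=str(row["patient_id"]),
            timepoint=tp,
            fraction=fraction,
            week=week,
            anesthesia=an,
            error=err,
            special_condition=special,
        )
    except ValueError as e:
        return (idx, str(e))


def read_cohort(
    path: str | Path, dialect_config: Mapping | None = None
) -> Cohort:
    """Read and validate a setup-error log from CSV.

    The CSV must carry the columns in :data:`CSV_COLUMNS` (``week`` and
    ``special_condition`` may be empty; a missing week is derived from the
    fraction number).  ``dialect_config`` is the ``io:`` config block and
    may set ``delimiter``, ``fractions_per_week`` and declare ``units``
    (which must be mm / deg — no silent conversion is attempted).

    Raises
    ------
    SchemaError
        if a required column is absent.
    ValidationError
        with row-level diagnostics if any row violates an invariant.
    """
    cfg = dict(dialect_config or {})
    units = cfg.get("units", {})
    if units.get("translation", "mm") != "mm" or units.get("rotation", "deg") != "deg":
        raise SchemaError(
            "only mm translations and deg rotations are supported; convert "
            "the log before loading"
        )
    fpw = int(cfg.get("fractions_per_week", 5))
    df = pd.read_csv(
        path,
        sep=cfg.get("delimiter", ","),
        dtype={"patient_id": str, "special_condition": str},
        float_precision="round_trip",
    )
    required = [c for c in CSV_COLUMNS if c not in ("week", "special_condition")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for opt in ("week", "special_condition"):
        if opt not in df.columns:
            df[opt] = None

    records: list[ScanRecord] = []
    errors: list[tuple[int | None, str]] = []
    for idx, row in df.iterrows():
        out = _coerce_row(row, int(idx), fpw)
        if isinstance(out, ScanRecord):
            records.append(out)
        else:
            errors.append(out)
    if errors:
        raise ValidationError(errors)
    cohort = Cohort(records=records, provenance=str(path))
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort as CSV, round-trippable by :func:`read_cohort`.

    Floats are written with ``repr`` precision, so values survive a
    write/read cycle bit-exactly.
    """
    cohort.validate()
    path = Path(path)
    df = cohort.to_frame()
    for col in ("x_mm", "y_mm", "z_mm", "yaw_deg", "roll_deg", "pitch_deg"):
        df[col] = df[col].map(repr)  # shortest exact decimal per value
    df.to_csv(path, index=False, lineterminator="\n")
    return path
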