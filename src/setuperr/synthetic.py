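"""Seeded synthetic setup-error cohorts.

The measured logs behind a clinical setup-uncertainty study are rarely
shareable, so every stage of this package is testable against a
generator that emulates the statistical structure such logs are assumed
to have:

* a per-patient *systematic* 6-DOF offset plus per-fraction *random*
  error before image-guided correction;
* small residual errors after correction (measured once per course by a
  repeat volumetric scan);
* weekly post-treatment errors = a residual-scale component plus an
  intrafractional increment, shrunk by a multiplier for anesthetized or
  sedated patients;
* a one-time paired planar (2D) measurement per designated patient,
  equal to the volumetric value shrunk by a net undercorrection factor
  plus measurement noise whose roll component is inflated.

All components are Gaussian; an optional heavy-tail contamination knob
mimics occasional outlier fractions (ill-fitting mask, uncooperative
patient).  Every draw comes from one seeded stream, so a given seed
yields a byte-identical cohort.

Default magnitudes are *calibrated, not measured*: they are chosen so
the full pipeline lands in the percentile bands clinical studies report
(95th percentile near 10 mm before correction, 1-1.5 mm after, about
2 mm by end of fraction), because per-DOF cohort variances are
generally unpublished.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .records import (
    Anesthesia,
    Cohort,
    EnrollmentRoster,
    ExclusionReason,
    RosterEntry,
    ScanRecord,
    SetupError6D,
    Timepoint,
    week_from_fraction,
)

_SIX = ("x", "y", "z", "yaw", "roll", "pitch")


def _vec6(trans: Sequence[float], rot: Sequence[float]) -> np.ndarray:
    return np.array(list(trans) + list(rot), dtype=float)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Translational SDs in mm, rotational SDs in degrees.  Each six-long
    SD vector is ordered x, y, z, yaw, roll, pitch.
    """

    n_patients: int = 165
    fractions_per_patient: int = 30
    fractions_per_week: int = 5
    #: per-patient systematic offset SDs (precorrection)
    systematic_sd: tuple = (1.5, 1.5, 1.5, 0.5, 0.5, 0.5)
    #: per-fraction random error SDs (precorrection)
    random_sd: tuple = (2.0, 2.0, 2.0, 0.6, 0.6, 0.6)
    #: residual error SDs after image-guided correction
    postcorrection_sd: tuple = (0.35, 0.35, 0.35, 0.2, 0.2, 0.2)
    #: intrafractional increment SDs (awake patients)
    intrafraction_sd: tuple = (0.36, 0.36, 0.36, 0.25, 0.25, 0.25)
    #: probability a patient is anesthetized / sedated
    anesthetized_fraction: float = 77 / 165
    sedated_fraction: float = 3 / 165
    #: multiplier (< 1) on intrafractional SDs under anesthesia or sedation
    anesthesia_multiplier: float = 0.6
    #: 2D (planar) measurement model; None means min(40, n_patients)
    n_2d_patients: int | None = None
    measurement_noise_sd: tuple = (0.3, 0.3, 0.3, 0.3, 0.3, 0.3)
    roll_inflation: float = 3.0
    #: net fractional undercorrection of the planar-suggested correction
    undercorrection: float = 0.15
    #: missingness of the research scans
    missing_postcorrection: float = 20 / 165
    missing_posttreatment: float = 0.3
    #: heavy-tail contamination: probability a fraction's random error is
    #: drawn at ``outlier_scale`` times its SD (default off)
    outlier_fraction: float = 0.0
    outlier_scale: float = 4.0
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_patients < 1 or self.fractions_per_patient < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.fractions_per_week < 1:
            raise ValueError("fractions_per_week must be >= 1")
        for name in (
            "systematic_sd", "random_sd", "postcorrection_sd",
            "intrafraction_sd", "measurement_noise_sd",
        ):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (6,) or np.any(v < 0):
                raise ValueError(f"{name} must be six nonnegative SDs")
        if not (0 < self.anesthesia_multiplier <= 1):
            raise ValueError("anesthesia_multiplier must be in (0, 1]")
        for name in (
            "anesthetized_fraction", "sedated_fraction",
            "missing_postcorrection", "missing_posttreatment",
            "outlier_fraction",
        ):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be a probability")
        if self.anesthetized_fraction + self.sedated_fraction > 1:
            raise ValueError("anesthetized + sedated fractions exceed 1")
        if not (0 <= self.undercorrection < 1):
            raise ValueError("undercorrection must be in [0, 1)")
        if self.roll_inflation < 1:
            raise ValueError("roll_inflation must be >= 1")
        if self.n_2d_patients is not None and self.n_2d_patients > self.n_patients:
            raise ValueError("n_2d_patients cannot exceed n_patients")
        return self

    @property
    def effective_n_2d(self) -> int:
        if self.n_2d_patients is None:
            return min(40, self.n_patients)
        return self.n_2d_patients


def _record(pid, tp, fraction, fpw, anesthesia, vec, special=None) -> ScanRecord:
    return ScanRecord(
        patient_id=pid,
        timepoint=tp,
        fraction=fraction,
        week=week_from_fraction(fraction, fpw),
        anesthesia=anesthesia,
        error=SetupError6D(*[float(v) for v in vec]),
        special_condition=special,
    )


def generate(config: GeneratorConfig) -> tuple[Cohort, dict]:
    """Generate a synthetic cohort and its ground-truth parameter record.

    Returns ``(cohort, truth)`` where ``truth`` echoes the configuration
    and adds the derived per-timepoint SDs and each patient's anesthesia
    status, for use in parameter-recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sys_sd = np.asarray(config.systematic_sd, dtype=float)
    rand_sd = np.asarray(config.random_sd, dtype=float)
    post_sd = np.asarray(config.postcorrection_sd, dtype=float)
    intra_sd = np.asarray(config.intrafraction_sd, dtype=float)
    meas_sd = np.asarray(config.measurement_noise_sd, dtype=float).copy()
    meas_sd[4] *= config.roll_inflation  # roll is the hard angle for 2D

    fpw = config.fractions_per_week
    n_weeks = week_from_fraction(config.fractions_per_patient, fpw)
    records: list[ScanRecord] = []
    statuses: dict[str, str] = {}

    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        u = rng.uniform()
        if u < config.anesthetized_fraction:
            an = Anesthesia.ANESTHETIZED
        elif u < config.anesthetized_fraction + config.sedated_fraction:
            an = Anesthesia.SEDATED
        else:
            an = Anesthesia.AWAKE
        statuses[pid] = an.value
        mult = 1.0 if an is Anesthesia.AWAKE else config.anesthesia_multiplier

        systematic = rng.normal(0.0, sys_sd)
        for frac in range(1, config.fractions_per_patient + 1):
            scale = 1.0
            if config.outlier_fraction and rng.uniform() < config.outlier_fraction:
                scale = config.outlier_scale
            pre = systematic + rng.normal(0.0, scale * rand_sd)
            special = "large motion flagged" if scale > 1.0 else None
            records.append(
                _record(pid, Timepoint.PRECORRECTION, frac, fpw, an, pre, special)
            )
            if frac == 1 and i < config.effective_n_2d:
                noise = rng.normal(0.0, meas_sd)
                twod = (1.0 - config.undercorrection) * pre + noise
                records.append(
                    _record(pid, Timepoint.ORTHOGONAL2D, frac, fpw, an, twod)
                )

        # one-time repeat scan after correction, possibly missed
        if rng.uniform() >= config.missing_postcorrection:
            resid = rng.normal(0.0, post_sd)
            records.append(
                _record(pid, Timepoint.POSTCORRECTION, 1, fpw, an, resid)
            )

        # weekly post-treatment scans: residual-scale error + intrafractional
        # increment (shrunk under anesthesia), at the last fraction of the week
        for w in range(1, n_weeks + 1):
            if rng.uniform() < config.missing_posttreatment:
                continue
            frac = min(w * fpw, config.fractions_per_patient)
            post = rng.normal(0.0, post_sd) + rng.normal(0.0, mult * intra_sd)
            records.append(
                _record(pid, Timepoint.POSTTREATMENT, frac, fpw, an, post)
            )

    cohort = Cohort(records=records, provenance=f"synthetic(seed={config.seed})")
    cohort.validate()
    truth = {
        "config": asdict(config),
        "anesthesia_status": statuses,
        "true_sd": {
            "precorrection": np.sqrt(sys_sd**2 + rand_sd**2).tolist(),
            "postcorrection": post_sd.tolist(),
            "posttreatment_awake": np.sqrt(post_sd**2 + intra_sd**2).tolist(),
            "posttreatment_anesthetized": np.sqrt(
                post_sd**2 + (config.anesthesia_multiplier * intra_sd) ** 2
            ).tolist(),
        },
    }
    return cohort, truth


def generate_scalar_panel(
    n_patients: int = 165,
    n_weeks: int = 6,
    effect: float = 0.0,
    baseline: float = 1.2,
    between_sd: float = 0.3,
    within_sd: float = 0.35,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Repeated-measures panel of scalar errors with a known group shift.

    Emulates the data the group-contrast models see: one representative
    scalar error per patient-week, with a patient random intercept
    (``between_sd``), residual noise (``within_sd``) and a pure location
    shift ``effect`` added to group 1.  Because the shift is in location,
    the true difference of *every* quantile, and of the mean, equals
    ``effect`` — which is what makes this panel a parameter-recovery
    fixture for both contrast targets.

    Returns a DataFrame with columns patient, group, week, value.
    """
    rng = np.random.default_rng(seed)
    pats = np.repeat(np.arange(n_patients), n_weeks)
    week = np.tile(np.arange(1, n_weeks + 1), n_patients)
    group_of = rng.permutation(np.arange(n_patients) % 2)
    g = group_of[pats]
    b = rng.normal(0.0, between_sd, size=n_patients)[pats]
    y = baseline + b + effect * g + rng.normal(0.0, within_sd, size=len(pats))
    return pd.DataFrame(
        {"patient": [f"P{p + 1:04d}" for p in pats], "group": g,
         "week": week, "value": y}
    )


def enrollment_roster(
    n_enrolled: int = 183,
    exclusions: dict[ExclusionReason, int] | None = None,
) -> EnrollmentRoster:
    """Roster emulating a study's enrollment bookkeeping.

    By default 183 enrolled patients with 18 exclusions (3 uncooperative,
    2 over the age limit, 1 spine-only course, 12 removed for machine
    downtime, capture errors or discretion), leaving 165 for analysis.
    """
    if exclusions is None:
        exclusions = {
            ExclusionReason.UNCOOPERATIVE: 3,
            ExclusionReason.OVER_AGE: 2,
            ExclusionReason.SPINE_ONLY: 1,
            ExclusionReason.DOWNTIME_OR_CAPTURE_ERROR_OR_DISCRETION: 12,
        }
    n_excl = sum(exclusions.values())
    if n_excl > n_enrolled:
        raise ValueError("more exclusions than enrolled patients")
    entries: list[RosterEntry] = []
    reasons: list[ExclusionReason] = []
    for reason, count in exclusions.items():
        reasons.extend([reason] * count)
    for i in range(n_enrolled):
        reason = reasons[i] if i < len(reasons) else None
        entries.append(
            RosterEntry(patient_id=f"E{i + 1:04d}", enrolled=True,
                        exclusion_reason=reason)
        )
    return EnrollmentRoster(entries=entries).validate()
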