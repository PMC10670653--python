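"""Monte Carlo scalarization of 6-DOF setup errors.

The six per-DOF error distributions are folded into three R-dependent
translational variances (see :mod:`setuperr.rigid`); a scalar sample of
the overall positional error is then the Euclidean norm of a 3-vector
drawn from independent normals centred on a measured error's
translations with those total variances.  Repeating the draw gives

* a *representative error* for each measurement (the mean sampled norm),
  comparable across timepoints and patient groups, and
* a cohort *percentile curve*: the 95th percentile of the sampled norm
  as a function of the isocenter-to-target distance R, with a bootstrap
  confidence band that resamples patients and re-estimates the
  variances.

The central object is :class:`SetupUncertaintyModel`, a scikit-learn
style estimator (``fit`` on an (n, 6) error matrix, then query curves
and samples); the module-level functions are thin wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .records import Cohort, SetupError6D, Timepoint
from .rigid import (
    DEFAULT_CONVENTION,
    RotationConvention,
    TransformedVariance,
    VarianceProfile,
    transform_variances,
)

CiMethod = Literal["percentile", "studentized"]

DEFAULT_R_GRID = (0.0, 25.0, 50.0, 75.0, 100.0)


def _as_rng(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


@dataclass(frozen=True)
class ScalarErrorSample:
    """One sampled scalar (norm) error in mm."""

    value: float
    R: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("a norm cannot be negative")


@dataclass
class PercentileCurve:
    """Percentile of scalar setup error vs isocenter-to-target distance.

    ``estimate[i]`` is the empirical percentile (default the 95th) of the
    sampled error norm at ``r_grid[i]``; ``lower``/``upper`` bound the
    bootstrap confidence band.
    """

    r_grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    percentile: float = 95.0
    n_sim: int = 2000
    n_boot: int = 500
    ci_method: str = "percentile"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r_grid must be strictly increasing")
        if np.any(self.lower > self.estimate + 1e-12) or np.any(
            self.estimate > self.upper + 1e-12
        ):
            raise ValueError("band must bracket the estimate at every R")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "R_mm": self.r_grid,
                "estimate_mm": self.estimate,
                "lower_mm": self.lower,
                "upper_mm": self.upper,
            }
        )


def draw_sample(
    error: SetupError6D,
    tv: TransformedVariance,
    rng: np.random.Generator | int | None = None,
) -> ScalarErrorSample:
    """Draw one scalar sample of the overall error for one measurement.

    Each translational component is drawn from a normal centred on the
    measured translation with the corresponding R-dependent total
    variance; the returned value is the Euclidean norm of the 3-vector.
    """
    rng = _as_rng(rng)
    sd = np.sqrt(tv.as_array())
    vec = rng.normal(error.translation, sd)
    return ScalarErrorSample(value=float(np.linalg.norm(vec)), R=tv.R)


def sample_lengths(
    means: np.ndarray, sd: np.ndarray, z: np.ndarray
) -> np.ndarray:
    """Norms of ``means + z * sd`` row-wise (all shaped (n, 3))."""
    return np.linalg.norm(means + z * sd, axis=1)


def representative_error(
    error: SetupError6D,
    tv: TransformedVariance,
    n_draws: int = 1000,
    rng: np.random.Generator | int | None = None,
    summary: Literal["mean", "median"] = "mean",
) -> float:
    """Representative scalar error for one measurement (mm).

    Repeats the scalar draw ``n_draws`` times (1000 by default) and
    summarises by the mean of the sampled norms; the median is available
    for robustness checks.  The mean is the default because downstream
    mixed models compare group means of these values.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = _as_rng(rng)
    sd = np.sqrt(tv.as_array())
    z = rng.normal(size=(n_draws, 3))
    vals = sample_lengths(error.translation[None, :], sd[None, :], z)
    return float(np.mean(vals) if summary == "mean" else np.median(vals))


class SetupUncertaintyModel(BaseEstimator):
    """Scalar setup-uncertainty model for one cohort timepoint.

    Fitting estimates the six per-DOF variances from an (n, 6) error
    matrix (columns x, y, z in mm; yaw, roll, pitch in degrees) with the
    unbiased (n-1) sample variance.  The fitted model then produces
    scalar error samples, per-measurement representative errors, and a
    percentile-vs-R curve with a patient-level bootstrap band.

    Parameters
    ----------
    r_grid : sequence of float
        Isocenter-to-target distances (mm) for the curve, strictly
        increasing; default 0 to 100 mm in steps of 25.
    percentile : float
        Percentile of the sampled norm to track (default 95).
    n_sim : int
        Scalar samples per R for the point estimate (default 2000).
    n_boot : int
        Bootstrap replicates for the confidence band (default 500).
    ci_method : {'percentile', 'studentized'}
        Bootstrap interval flavour; both are offered because published
        analyses of this design have described each.
    mode : {'first_order', 'as_printed', 'exact_mc'}
        Variance-transform mode, see :func:`setuperr.rigid.transform_variances`.
    convention : RotationConvention or None
        Machine rotation convention; None uses the default couch
        convention.
    ci_level : float
        Confidence level of the band (default 0.95).
    random_state : int, Generator or None
        Seeds every draw; fixing it makes all outputs bit-reproducible.

    Attributes
    ----------
    variance_profile_ : VarianceProfile
        Estimated per-DOF variances (mm^2 / rad^2).
    errors_ : ndarray of shape (n_records, 6)
        The fitted error matrix.
    groups_ : ndarray of shape (n_records,)
        Patient label per record (used by the bootstrap).
    n_patients_ : int
    """

    def __init__(
        self,
        r_grid: Sequence[float] = DEFAULT_R_GRID,
        percentile: float = 95.0,
        n_sim: int = 2000,
        n_boot: int = 500,
        ci_method: CiMethod = "percentile",
        mode: str = "first_order",
        convention: RotationConvention | None = None,
        ci_level: float = 0.95,
        random_state=None,
    ):
        self.r_grid = r_grid
        self.percentile = percentile
        self.n_sim = n_sim
        self.n_boot = n_boot
        self.ci_method = ci_method
        self.mode = mode
        self.convention = convention
        self.ci_level = ci_level
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None, groups=None) -> "SetupUncertaintyModel":
        """Estimate per-DOF variances from measured errors.

        ``X`` may be an (n, 6) array or a :class:`~setuperr.records.Cohort`
        (in which case patient labels are taken from the records and
        ``groups`` is ignored).  ``groups`` labels records by patient for
        the bootstrap; records without labels are treated as one patient
        each.
        """
        if isinstance(X, Cohort):
            groups = np.array([r.patient_id for r in X.records])
            X = X.dof_matrix()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 6:
            raise ValueError("X must be an (n, 6) DOF error matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        n = X.shape[0]
        if groups is None:
            groups = np.arange(n)
        groups = np.asarray(groups)
        if groups.shape != (n,):
            raise ValueError("groups must have one label per record")
        if len(np.unique(groups)) < 2:
            raise ValueError(
                "need records from at least 2 patients to estimate cohort "
                "variances and bootstrap them"
            )
        self.errors_ = X.copy()
        self.groups_ = groups.copy()
        self.n_records_ = n
        self.n_patients_ = len(np.unique(groups))
        self.variance_profile_ = VarianceProfile.from_dof_matrix(X)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "variance_profile_"):
            raise RuntimeError("model is not fitted; call fit() first")

    def _convention(self) -> RotationConvention:
        return self.convention if self.convention is not None else DEFAULT_CONVENTION

    def transformed_variance(
        self, R: float, profile: VarianceProfile | None = None
    ) -> TransformedVariance:
        """Total translational variances at distance R (fitted profile)."""
        self._check_fitted()
        return transform_variances(
            profile or self.variance_profile_, R,
            mode=self.mode, convention=self._convention(),
        )

    # -- sampling ---------------------------------------------------------

    def sample(self, R: float, n: int, rng=None) -> np.ndarray:
        """Draw ``n`` scalar error samples (mm) at distance R.

        Each draw first picks one fitted record uniformly at random (its
        measured translations become the means), then samples the
        3-vector and returns its norm.
        """
        self._check_fitted()
        rng = _as_rng(self.random_state if rng is None else rng)
        sd = np.sqrt(self.transformed_variance(R).as_array())
        idx = rng.integers(0, self.n_records_, size=n)
        z = rng.normal(size=(n, 3))
        return sample_lengths(self.errors_[idx, :3], sd[None, :], z)

    def representative_errors(
        self, R: float = 0.0, n_draws: int = 1000, rng=None,
        summary: Literal["mean", "median"] = "mean",
    ) -> np.ndarray:
        """Representative scalar error per fitted record at distance R."""
        self._check_fitted()
        rng = _as_rng(self.random_state if rng is None else rng)
        tv = self.transformed_variance(R)
        sd = np.sqrt(tv.as_array())
        z = rng.normal(size=(self.n_records_, n_draws, 3))
        vals = np.linalg.norm(
            self.errors_[:, None, :3] + z * sd[None, None, :], axis=2
        )
        return vals.mean(axis=1) if summary == "mean" else np.median(vals, axis=1)

    # -- percentile curve -------------------------------------------------

    def _curve_point(
        self,
        trans: np.ndarray,
        profile: VarianceProfile,
        r_grid: np.ndarray,
        idx: np.ndarray,
        z: np.ndarray,
        conv: RotationConvention,
    ) -> np.ndarray:
        """Percentile at each R from common random numbers (idx, z).

        Reusing one set of record indices and standard-normal draws across
        the R grid makes the estimated curve exactly flat when rotational
        variance is zero and suppresses spurious non-monotonicity from
        Monte Carlo noise.
        """
        q = np.empty(len(r_grid))
        for i, R in enumerate(r_grid):
            p = transform_variances(profile, R, mode=self.mode, convention=conv)
            vals = sample_lengths(trans[idx], np.sqrt(p.as_array())[None, :], z)
            q[i] = np.percentile(vals, self.percentile)
        return q

    def _replicate(
        self,
        X: np.ndarray,
        groups: np.ndarray,
        r_grid: np.ndarray,
        conv: RotationConvention,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """One patient-bootstrap replicate: resampled data and its curve.

        Patients drawn more than once are relabelled as distinct, so a
        nested bootstrap sees the resampled cohort's own structure.
        """
        patients = np.unique(groups)
        chosen = rng.choice(patients, size=len(patients), replace=True)
        row_blocks = [np.flatnonzero(groups == p) for p in chosen]
        rows = np.concatenate(row_blocks)
        gb = np.repeat(np.arange(len(chosen)), [len(b) for b in row_blocks])
        Xb = X[rows]
        profile_b = VarianceProfile.from_dof_matrix(Xb)
        idx_b = rng.integers(0, len(rows), size=self.n_sim)
        z_b = rng.normal(size=(self.n_sim, 3))
        q = self._curve_point(Xb[:, :3], profile_b, r_grid, idx_b, z_b, conv)
        return Xb, gb, q

    def percentile_curve(self, n_inner: int = 20) -> PercentileCurve:
        """Estimate the percentile-vs-R curve with a bootstrap band.

        The point estimate draws ``n_sim`` scalar samples per R.  The
        band comes from ``n_boot`` bootstrap replicates that resample
        *patients* with replacement (respecting repeated measures),
        re-estimate the variance profile, and recompute the percentile.
        The ``studentized`` interval is the bootstrap-t: each replicate's
        pivot is standardized by a nested patient bootstrap of size
        ``n_inner`` run inside that replicate.
        """
        self._check_fitted()
        rng = _as_rng(self.random_state)
        r_grid = np.asarray(self.r_grid, dtype=float)
        if np.any(r_grid < 0) or np.any(np.diff(r_grid) <= 0):
            raise ValueError("r_grid must be nonnegative and strictly increasing")
        if self.ci_method not in ("percentile", "studentized"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")
        conv = self._convention()
        trans = self.errors_[:, :3]
        studentized = self.ci_method == "studentized"

        idx = rng.integers(0, self.n_records_, size=self.n_sim)
        z = rng.normal(size=(self.n_sim, 3))
        est = self._curve_point(trans, self.variance_profile_, r_grid, idx, z, conv)

        boot_q = np.empty((self.n_boot, len(r_grid)))
        boot_se = np.empty((self.n_boot, len(r_grid)))
        for b in range(self.n_boot):
            Xb, gb, boot_q[b] = self._replicate(
                self.errors_, self.groups_, r_grid, conv, rng
            )
            if studentized:
                inner = np.empty((n_inner, len(r_grid)))
                for j in range(n_inner):
                    _, _, inner[j] = self._replicate(Xb, gb, r_grid, conv, rng)
                boot_se[b] = inner.std(axis=0, ddof=1)

        alpha = 1.0 - self.ci_level
        if self.n_boot == 0:
            lower = upper = est.copy()
        elif not studentized:
            lower = np.percentile(boot_q, 100 * alpha / 2, axis=0)
            upper = np.percentile(boot_q, 100 * (1 - alpha / 2), axis=0)
        else:
            se_hat = boot_q.std(axis=0, ddof=1)
            lower = np.empty(len(r_grid))
            upper = np.empty(len(r_grid))
            for i in range(len(r_grid)):
                if se_hat[i] == 0:
                    lower[i] = upper[i] = est[i]
                    continue
                with np.errstate(divide="ignore", invalid="ignore"):
                    tstat = (boot_q[:, i] - est[i]) / np.where(
                        boot_se[:, i] > 0, boot_se[:, i], np.nan
                    )
                tstat = tstat[np.isfinite(tstat)]
                tl = np.percentile(tstat, 100 * alpha / 2)
                tu = np.percentile(tstat, 100 * (1 - alpha / 2))
                lower[i] = est[i] - tu * se_hat[i]
                upper[i] = est[i] - tl * se_hat[i]

        # a finite bootstrap can place both band edges on one side of the
        # point estimate; widen minimally so the band always brackets it
        lower = np.minimum(lower, est)
        upper = np.maximum(upper, est)
        seed = self.random_state if isinstance(self.random_state, int) else None
        return PercentileCurve(
            r_grid=r_grid, estimate=est, lower=lower, upper=upper,
            percentile=self.percentile, n_sim=self.n_sim, n_boot=self.n_boot,
            ci_method=self.ci_method, seed=seed,
        )


def representative_error_table(
    cohort: Cohort,
    timepoint: Timepoint | str,
    R: float = 0.0,
    n_draws: int = 1000,
    mode: str = "first_order",
    convention: RotationConvention | None = None,
    random_state=None,
    summary: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Representative scalar error per record at one timepoint.

    Estimates the timepoint's variance profile from all of its records,
    then summarises ``n_draws`` scalar samples per record.  Returns a
    DataFrame with patient_id, week, anesthesia, timepoint and the
    representative value in mm — the input the group-contrast models take.
    """
    sub = cohort.select(timepoint=timepoint)
    if len(sub) == 0:
        raise ValueError(
            f"cohort has no records at timepoint {Timepoint(timepoint).value!r}"
        )
    model = SetupUncertaintyModel(
        mode=mode, convention=convention, random_state=random_state
    )
    model.fit(sub)
    vals = model.representative_errors(R=R, n_draws=n_draws, summary=summary)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in sub.records],
            "week": [r.week for r in sub.records],
            "anesthesia": [r.anesthesia.value for r in sub.records],
            "timepoint": [r.timepoint.value for r in sub.records],
            "value_mm": vals,
        }
    )


def percentile_curve(
    cohort: Cohort,
    timepoint: Timepoint | str,
    r_grid: Sequence[float] = DEFAULT_R_GRID,
    n_sim: int = 2000,
    n_boot: int = 500,
    ci_method: CiMethod = "percentile",
    mode: str = "first_order",
    convention: RotationConvention | None = None,
    random_state=None,
    percentile: float = 95.0,
) -> PercentileCurve:
    """Percentile-vs-R curve for one timepoint of a cohort.

    Thin wrapper over :class:`SetupUncertaintyModel`; see its docs.
    """
    sub = cohort.select(timepoint=timepoint)
    if len(sub) == 0:
        raise ValueError(
            f"cohort has no records at timepoint {Timepoint(timepoint).value!r}"
        )
    model = SetupUncertaintyModel(
        r_grid=r_grid, percentile=percentile, n_sim=n_sim, n_boot=n_boot,
        ci_method=ci_method, mode=mode, convention=convention,
        random_state=random_state,
    )
    model.fit(sub)
    return model.percentile_curve()
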