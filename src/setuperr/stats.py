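"""Cohort statistics for setup-error analyses.

Implements the comparisons a setup-uncertainty study runs on its logs:

* per-DOF distribution summaries by timepoint;
* paired planar-vs-volumetric (2D vs 3D) tests: exact Wilcoxon
  signed-rank per DOF and two-sided F-tests on the variances of the
  difference distributions, with Shapiro-Wilk normality gating and
  step-down Holm correction within same-unit families;
* group contrasts of representative scalar errors (mean via a linear
  mixed model with a patient random intercept; 95th percentile via
  linear quantile regression with a patient-level bootstrap), exposed
  as the scikit-learn style :class:`GroupContrast` estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .records import Cohort, DOF_NAMES, ROTATION_DOFS, TRANSLATION_DOFS, Timepoint

Target = Literal["mean", "quantile95"]


def _as_rng(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


# ---------------------------------------------------------------------------
# summaries


def summarize_dof(cohort: Cohort, timepoint: Timepoint | str) -> pd.DataFrame:
    """Per-DOF summary of one timepoint's error distributions.

    Returns a DataFrame indexed by DOF (x, y, z in mm; yaw, roll, pitch in
    deg) with n, mean, sd, median and the 2.5th/95th/97.5th percentiles.
    """
    sub = cohort.select(timepoint=timepoint)
    if len(sub) == 0:
        raise ValueError(
            f"no records at timepoint {Timepoint(timepoint).value!r}"
        )
    X = sub.dof_matrix()
    rows = {}
    for j, name in enumerate(DOF_NAMES):
        col = X[:, j]
        rows[name] = {
            "n": len(col),
            "mean": np.mean(col),
            "sd": np.std(col, ddof=1) if len(col) > 1 else 0.0,
            "median": np.median(col),
            "p2.5": np.percentile(col, 2.5),
            "p95": np.percentile(col, 95),
            "p97.5": np.percentile(col, 97.5),
        }
    df = pd.DataFrame(rows).T
    df.index.name = "dof"
    df["n"] = df["n"].astype(int)
    return df


# ---------------------------------------------------------------------------
# paired 2D vs 3D differences


@dataclass
class PairedDifferenceSet:
    """Per-patient 6-DOF differences, planar (2D) minus volumetric (3D)."""

    patient_ids: list[str]
    differences: pd.DataFrame  # columns DOF_NAMES, one row per patient

    def __post_init__(self) -> None:
        if list(self.differences.columns) != list(DOF_NAMES):
            raise ValueError(f"difference columns must be {DOF_NAMES}")
        if len(self.patient_ids) != len(self.differences):
            raise ValueError("one difference row per patient required")

    def __len__(self) -> int:
        return len(self.differences)

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "PairedDifferenceSet":
        """Pair each planar record with the volumetric scan of the same
        patient and fraction and difference them (2D minus 3D).

        Patients lacking either member of the pair are skipped.
        """
        by_key = {
            (r.patient_id, r.fraction): r
            for r in cohort.records
            if r.timepoint is Timepoint.PRECORRECTION
        }
        ids, rows = [], []
        for r in cohort.records:
            if r.timepoint is not Timepoint.ORTHOGONAL2D:
                continue
            mate = by_key.get((r.patient_id, r.fraction))
            if mate is None:
                continue
            ids.append(r.patient_id)
            rows.append(r.error.as_array() - mate.error.as_array())
        if not rows:
            return cls(patient_ids=[], differences=pd.DataFrame(columns=DOF_NAMES))
        return cls(
            patient_ids=ids,
            differences=pd.DataFrame(np.vstack(rows), columns=DOF_NAMES),
        )


@dataclass
class TestReport:
    """Hypothesis-level results with raw and Holm-adjusted p-values."""

    name: str
    table: pd.DataFrame  # hypothesis, statistic, n, p_raw, p_holm, reject
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "alpha": self.alpha,
            "notes": self.notes,
            "hypotheses": self.table.to_dict(orient="records"),
        }


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment of a family of p-values.

    Sorts ascending, multiplies the k-th smallest by (m - k), enforces
    monotonicity cumulatively and caps at 1.  Controls the family-wise
    error rate under arbitrary dependence.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def paired_wilcoxon(
    pairs: PairedDifferenceSet,
    alpha: float = 0.05,
    exact_cutoff: int = 25,
    continuity_correction: bool = True,
) -> TestReport:
    """Paired Wilcoxon signed-rank test of 2D vs 3D per DOF.

    Tests, for each of the six DOFs, whether the planar-minus-volumetric
    differences are symmetric about zero.  The exact null distribution is
    used up to ``exact_cutoff`` non-zero differences; above that the
    normal approximation (with continuity correction if requested) takes
    over.  Zero differences are dropped, with the count noted.  The six
    p-values form one Holm family.
    """
    if len(pairs) < 5:
        raise ValueError("need at least 5 paired patients")
    notes: list[str] = []
    stats_, ns, praw = [], [], []
    for name in DOF_NAMES:
        d = pairs.differences[name].to_numpy(dtype=float)
        nz = d[d != 0]
        dropped = len(d) - len(nz)
        if dropped:
            notes.append(f"{name}: dropped {dropped} zero difference(s)")
        if len(nz) == 0:
            warnings.warn(
                f"all {name} differences are zero; p set to 1", stacklevel=2
            )
            stats_.append(np.nan)
            ns.append(0)
            praw.append(1.0)
            continue
        method = "exact" if len(nz) <= exact_cutoff else "approx"
        res = sps.wilcoxon(
            nz,
            zero_method="wilcox",
            correction=continuity_correction,
            method=method,
        )
        stats_.append(float(res.statistic))
        ns.append(len(nz))
        praw.append(float(res.pvalue))
    padj = holm_adjust(praw)
    table = pd.DataFrame(
        {
            "hypothesis": [f"2D-3D {n} symmetric about 0" for n in DOF_NAMES],
            "dof": DOF_NAMES,
            "statistic": stats_,
            "n": ns,
            "p_raw": praw,
            "p_holm": padj,
            "reject": padj < alpha,
        }
    )
    return TestReport(name="paired_wilcoxon_2d_vs_3d", table=table,
                      alpha=alpha, notes=notes)


_FAMILIES = {
    "translations": TRANSLATION_DOFS,
    "rotations": ROTATION_DOFS,
}


def variance_equality_tests(
    pairs: PairedDifferenceSet, alpha: float = 0.05
) -> TestReport:
    """Two-sided F-tests comparing DOF variances of the 2D-3D differences.

    Same-unit DOFs are compared pairwise (three translation pairs, three
    rotation pairs); translations are never compared against rotations.
    Each family is gated on Shapiro-Wilk normality of its member
    distributions at ``alpha``: if any member fails, the family's F-tests
    are marked invalid and no p-values are emitted for it.  Holm
    correction is applied within each family.
    """
    if len(pairs) < 5:
        raise ValueError("need at least 5 paired patients")
    notes: list[str] = []
    rows: list[dict] = []
    for fam, dofs in _FAMILIES.items():
        sw_pass = True
        for name in dofs:
            d = pairs.differences[name].to_numpy(dtype=float)
            swp = float(sps.shapiro(d).pvalue)
            notes.append(f"shapiro {name}: p={swp:.4g}")
            if swp < alpha:
                sw_pass = False
        fam_rows = []
        for i, a in enumerate(dofs):
            for b in dofs[i + 1:]:
                da = pairs.differences[a].to_numpy(dtype=float)
                db = pairs.differences[b].to_numpy(dtype=float)
                va, vb = np.var(da, ddof=1), np.var(db, ddof=1)
                F = va / vb
                dfn, dfd = len(da) - 1, len(db) - 1
                p = 2 * min(sps.f.cdf(F, dfn, dfd), sps.f.sf(F, dfn, dfd))
                p = min(1.0, float(p))
                fam_rows.append(
                    {
                        "hypothesis": f"var({a}) = var({b})",
                        "family": fam,
                        "statistic": F,
                        "df": (dfn, dfd),
                        "p_raw": p if sw_pass else np.nan,
                        "valid": sw_pass,
                    }
                )
        if sw_pass:
            padj = holm_adjust([r["p_raw"] for r in fam_rows])
            for r, pa in zip(fam_rows, padj):
                r["p_holm"] = pa
                r["reject"] = pa < alpha
        else:
            notes.append(
                f"{fam}: normality gate failed; F-test invalid, no p emitted"
            )
            for r in fam_rows:
                r["p_holm"] = np.nan
                r["reject"] = False
        rows.extend(fam_rows)
    table = pd.DataFrame(rows)
    return TestReport(name="variance_equality_2d_vs_3d", table=table,
                      alpha=alpha, notes=notes)


# ---------------------------------------------------------------------------
# group contrasts of representative scalar errors


@dataclass
class ContrastFit:
    """A fitted two-group contrast of representative scalar errors."""

    effect: float  # mm, group[1] minus group[0]
    se: float
    pvalue: float
    conf_int: tuple[float, float]
    target: str
    group_labels: tuple[str, str]
    n_obs: int
    n_patients: int
    converged: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "effect_mm": self.effect,
            "se_mm": self.se,
            "pvalue": self.pvalue,
            "conf_int_mm": list(self.conf_int),
            "target": self.target,
            "groups": list(self.group_labels),
            "n_obs": self.n_obs,
            "n_patients": self.n_patients,
            "converged": self.converged,
            "note": self.note,
        }


class GroupContrast(BaseEstimator):
    """Two-group contrast of repeated scalar measurements per patient.

    ``target='mean'`` fits a linear mixed model with a patient random
    intercept (weekly repeats and missing timepoints are handled
    naturally) and reports the fixed group effect with its Wald interval.
    ``target='quantile95'`` fits a linear quantile regression at tau and
    reports the group coefficient with a patient-level bootstrap interval,
    since the repeated measures violate the iid assumptions behind the
    analytic quantile-regression covariance.

    Parameters
    ----------
    target : {'mean', 'quantile95'}
    tau : float
        Quantile for the quantile target (default 0.95).
    ci_level : float
        Confidence level (default 0.95).
    n_boot : int
        Patient-bootstrap replicates for the quantile target (default 200).
    random_state : int, Generator or None

    Attributes
    ----------
    effect_, se_, pvalue_, conf_int_, converged_, group_labels_
    """

    def __init__(
        self,
        target: Target = "mean",
        tau: float = 0.95,
        ci_level: float = 0.95,
        n_boot: int = 200,
        random_state=None,
    ):
        self.target = target
        self.tau = tau
        self.ci_level = ci_level
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y, groups) -> "GroupContrast":
        """Fit the contrast.

        ``X`` holds the group label of each observation (any hashable;
        exactly two levels), ``y`` the representative scalar errors (mm),
        ``groups`` the patient identifier of each observation.
        """
        if not (0 < self.tau < 1):
            raise ValueError("tau must lie in (0, 1)")
        g = np.asarray(X).ravel()
        y = np.asarray(y, dtype=float).ravel()
        pats = np.asarray(groups).ravel()
        if not (len(g) == len(y) == len(pats)):
            raise ValueError("X, y and groups must have equal length")
        levels = sorted(set(g.tolist()), key=str)
        if len(levels) < 2:
            raise ValueError("contrast requires two groups; got one")
        if len(levels) > 2:
            raise ValueError(
                f"contrast requires exactly two groups, got {len(levels)}"
            )
        for lev in levels:
            if len(np.unique(pats[g == lev])) < 2:
                raise ValueError(
                    f"group {lev!r} needs at least 2 patients"
                )
        ind = (g == levels[1]).astype(float)
        exog = sm.add_constant(ind)
        self.group_labels_ = (str(levels[0]), str(levels[1]))
        self.n_obs_ = len(y)
        self.n_patients_ = len(np.unique(pats))
        self.converged_ = True
        self.note_ = ""
        alpha = 1.0 - self.ci_level

        if self.target == "mean":
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fit = sm.MixedLM(y, exog, groups=pats).fit(reml=True)
            if any("onverge" in str(w.message) for w in caught) or not fit.converged:
                self.converged_ = False
                self.note_ = "mixed-model fit did not fully converge"
            self.effect_ = float(fit.params[1])
            self.se_ = float(fit.bse[1])
            self.pvalue_ = float(fit.pvalues[1])
            ci = fit.conf_int(alpha=alpha)
            self.conf_int_ = (float(ci[1][0]), float(ci[1][1]))
        elif self.target == "quantile95":
            rng = _as_rng(self.random_state)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                qfit = sm.QuantReg(y, exog).fit(q=self.tau)
            self.effect_ = float(qfit.params[1])
            uniq = np.unique(pats)
            rows_of = {p: np.flatnonzero(pats == p) for p in uniq}
            boots = []
            attempts = 0
            while len(boots) < self.n_boot and attempts < 5 * self.n_boot:
                attempts += 1
                chosen = rng.choice(uniq, size=len(uniq), replace=True)
                rows = np.concatenate([rows_of[p] for p in chosen])
                gb, yb = ind[rows], y[rows]
                if gb.min() == gb.max():
                    continue  # replicate lost one group entirely
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    bfit = sm.QuantReg(yb, sm.add_constant(gb)).fit(q=self.tau)
                boots.append(float(bfit.params[1]))
            if len(boots) < self.n_boot:
                self.converged_ = False
                self.note_ = "patient bootstrap produced too few usable replicates"
            boots = np.asarray(boots)
            self.se_ = float(boots.std(ddof=1)) if len(boots) > 1 else np.nan
            lo = float(np.percentile(boots, 100 * alpha / 2))
            hi = float(np.percentile(boots, 100 * (1 - alpha / 2)))
            self.conf_int_ = (min(lo, self.effect_), max(hi, self.effect_))
            if self.se_ and np.isfinite(self.se_) and self.se_ > 0:
                z = self.effect_ / self.se_
                self.pvalue_ = float(2 * sps.norm.sf(abs(z)))
            else:
                self.pvalue_ = np.nan
        else:
            raise ValueError(f"unknown target {self.target!r}")
        return self

    def report(self) -> ContrastFit:
        if not hasattr(self, "effect_"):
            raise RuntimeError("contrast is not fitted; call fit() first")
        return ContrastFit(
            effect=self.effect_,
            se=self.se_,
            pvalue=self.pvalue_,
            conf_int=self.conf_int_,
            target=self.target,
            group_labels=self.group_labels_,
            n_obs=self.n_obs_,
            n_patients=self.n_patients_,
            converged=self.converged_,
            note=self.note_,
        )


def fit_group_contrast(
    values: Sequence[float],
    group: Sequence,
    patient: Sequence,
    target: Target = "mean",
    tau: float = 0.95,
    ci_level: float = 0.95,
    n_boot: int = 200,
    random_state=None,
) -> ContrastFit:
    """Fit a two-group contrast of representative scalar errors.

    Thin wrapper over :class:`GroupContrast`; see its docs.  Returns the
    serializable :class:`ContrastFit`.
    """
    est = GroupContrast(
        target=target, tau=tau, ci_level=ci_level, n_boot=n_boot,
        random_state=random_state,
    )
    est.fit(group, values, patient)
    return est.report()
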