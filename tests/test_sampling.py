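"""Scalar error sampling, representative errors and percentile curves."""

import numpy as np
import pytest
import scipy.stats as sps
from sklearn.base import clone

from setuperr import (
    SetupError6D,
    SetupUncertaintyModel,
    TransformedVariance,
    draw_sample,
    percentile_curve,
    representative_error,
    representative_error_table,
)
from setuperr.synthetic import GeneratorConfig, generate

CHI3_P95 = float(np.sqrt(sps.chi2.ppf(0.95, df=3)))  # ~2.7955
CHI3_MEAN = float(np.sqrt(8 / np.pi))  # ~1.5958


def tv(p=(1.0, 1.0, 1.0), R=0.0):
    return TransformedVariance(p_x=p[0], p_y=p[1], p_z=p[2], R=R, mode="test")


class TestDrawSample:
    def test_degenerate_normals_return_translation_norm(self, rng):
        err = SetupError6D(3, 0, 0, 0, 0, 0)
        s = draw_sample(err, tv(p=(0, 0, 0)), rng)
        assert s.value == 3.0

    def test_zero_everything_is_zero_even_with_rotational_variance(self, rng):
        # at R=0 the rotational variances never reach the sampler
        err = SetupError6D(0, 0, 0, 2, 2, 2)
        s = draw_sample(err, tv(p=(0, 0, 0), R=0.0), rng)
        assert s.value == 0.0

    def test_unit_isotropic_norm_matches_chi3(self, rng):
        err = SetupError6D(0, 0, 0, 0, 0, 0)
        n = 200_000
        z = rng.normal(size=(n, 3))
        vals = np.linalg.norm(z, axis=1)
        se_p95 = np.sqrt(0.95 * 0.05 / n) / sps.chi(3).pdf(CHI3_P95)
        assert np.percentile(vals, 95) == pytest.approx(CHI3_P95, abs=3 * se_p95)
        se_mean = vals.std() / np.sqrt(n)
        assert vals.mean() == pytest.approx(CHI3_MEAN, abs=3 * se_mean)


class TestRepresentativeError:
    def test_pythagoras_when_degenerate(self, rng):
        err = SetupError6D(0, 3, 4, 0, 0, 0)
        for n in (1, 10):
            assert representative_error(err, tv(p=(0, 0, 0)), n, rng) == 5.0

    def test_homogeneous_in_translations(self, rng):
        err1 = SetupError6D(1, 2, 2, 0, 0, 0)
        err2 = SetupError6D(2, 4, 4, 0, 0, 0)
        v1 = representative_error(err1, tv(p=(0, 0, 0)), 10, rng)
        v2 = representative_error(err2, tv(p=(0, 0, 0)), 10, rng)
        assert v2 == pytest.approx(2 * v1)

    def test_zero_mean_isotropic_mean_is_chi3_mean(self, rng):
        err = SetupError6D(0, 0, 0, 0, 0, 0)
        v = representative_error(err, tv(p=(1, 1, 1)), 200_000, rng)
        assert v == pytest.approx(CHI3_MEAN, abs=0.01)

    def test_median_summary_smaller_than_mean_for_skewed_norm(self, rng):
        err = SetupError6D(0, 0, 0, 0, 0, 0)
        m = representative_error(err, tv(p=(1, 1, 1)), 50_000, rng, "mean")
        md = representative_error(err, tv(p=(1, 1, 1)), 50_000, rng, "median")
        assert md < m


class TestModelFit:
    def test_requires_six_columns(self):
        with pytest.raises(ValueError, match=r"\(n, 6\)"):
            SetupUncertaintyModel().fit(np.zeros((4, 3)))

    def test_requires_two_patients(self):
        X = np.zeros((5, 6))
        with pytest.raises(ValueError, match="2 patients"):
            SetupUncertaintyModel().fit(X, groups=np.zeros(5))

    def test_sklearn_clone_roundtrip(self):
        m = SetupUncertaintyModel(n_sim=123, ci_method="studentized")
        c = clone(m)
        assert c.get_params()["n_sim"] == 123
        assert c.get_params()["ci_method"] == "studentized"

    def test_variance_profile_uses_unbiased_estimator(self, small_cohort):
        cohort, _ = small_cohort
        sub = cohort.select(timepoint="precorrection")
        m = SetupUncertaintyModel().fit(sub)
        X = sub.dof_matrix()
        assert m.variance_profile_.var_x == pytest.approx(
            X[:, 0].var(ddof=1)
        )
        assert m.variance_profile_.var_yaw == pytest.approx(
            np.deg2rad(X[:, 3].std(ddof=1)) ** 2
        )


class TestPercentileCurve:
    def test_zero_cohort_gives_zero_curve_and_band(self, zero_cohort):
        c = percentile_curve(zero_cohort, "precorrection",
                             n_sim=200, n_boot=20, random_state=0)
        assert np.all(c.estimate == 0)
        assert np.all(c.lower == 0) and np.all(c.upper == 0)

    def test_flat_without_rotational_variance(self):
        cfg = GeneratorConfig(
            n_patients=10,
            systematic_sd=(1.5, 1.5, 1.5, 0, 0, 0),
            random_sd=(2, 2, 2, 0, 0, 0),
            postcorrection_sd=(0.35, 0.35, 0.35, 0, 0, 0),
            intrafraction_sd=(0.36, 0.36, 0.36, 0, 0, 0),
            seed=3,
        )
        cohort, _ = generate(cfg)
        c = percentile_curve(cohort, "precorrection",
                             n_sim=500, n_boot=10, random_state=5)
        assert np.ptp(c.estimate) == 0.0  # exactly flat in R

    def test_monotone_with_rotational_variance(self, small_cohort):
        cohort, _ = small_cohort
        for tp in ("precorrection", "posttreatment"):
            c = percentile_curve(cohort, tp, n_sim=1500, n_boot=10,
                                 random_state=7)
            assert np.all(np.diff(c.estimate) >= 0)

    def test_isotropic_translations_match_chi3_quantile(self):
        # zero rotations, unit translational variance: the curve is flat at
        # the 95th percentile of a chi-3 scaled by sqrt(2) — the sampler
        # centres draws on measured values AND adds the cohort variance
        rng = np.random.default_rng(21)
        n = 4000
        X = np.zeros((n, 6))
        X[:, :3] = rng.normal(0, 1.0, size=(n, 3))
        m = SetupUncertaintyModel(n_sim=20_000, n_boot=0, random_state=2).fit(
            X, groups=np.arange(n) % 50
        )
        c = m.percentile_curve()
        sd_eff = np.sqrt(1 + X[:, :3].var(axis=0, ddof=1).mean())
        assert np.ptp(c.estimate) == 0.0
        assert c.estimate[0] == pytest.approx(CHI3_P95 * sd_eff, rel=0.03)

    def test_r0_depends_only_on_translations(self, small_cohort):
        cohort, _ = small_cohort
        sub = cohort.select(timepoint="precorrection")
        m1 = SetupUncertaintyModel(n_sim=800, n_boot=0, random_state=9).fit(sub)
        X = m1.errors_.copy()
        X[:, 3:] = 0.0
        m2 = SetupUncertaintyModel(n_sim=800, n_boot=0, random_state=9).fit(
            X, groups=m1.groups_
        )
        assert m1.percentile_curve().estimate[0] == m2.percentile_curve().estimate[0]

    def test_seed_fixes_every_output(self, small_cohort):
        cohort, _ = small_cohort
        kw = dict(n_sim=400, n_boot=30, random_state=13)
        c1 = percentile_curve(cohort, "postcorrection", **kw)
        c2 = percentile_curve(cohort, "postcorrection", **kw)
        for a, b in ((c1.estimate, c2.estimate), (c1.lower, c2.lower),
                     (c1.upper, c2.upper)):
            assert np.array_equal(a, b)

    def test_band_brackets_estimate_both_ci_methods(self, small_cohort):
        cohort, _ = small_cohort
        widths = {}
        for ci in ("percentile", "studentized"):
            c = percentile_curve(cohort, "postcorrection", n_sim=800,
                                 n_boot=80, ci_method=ci, random_state=17)
            assert np.all(c.lower <= c.estimate) and np.all(c.estimate <= c.upper)
            widths[ci] = np.mean(c.upper - c.lower)
        # the two flavours should produce bands of the same order
        assert 0.3 < widths["studentized"] / widths["percentile"] < 3.0

    def test_band_covers_known_quantile(self):
        # synthetic cohorts with known generating parameters: the 95% band
        # should usually contain the true 95th percentile (reduced replicate
        # count and n_boot keep this quick; the rate is checked loosely)
        sd = 0.5
        true_q = CHI3_P95 * np.sqrt(2) * sd  # measured mean + cohort variance
        hits = 0
        n_rep = 15
        for i in range(n_rep):
            rng = np.random.default_rng(100 + i)
            X = np.zeros((300, 6))
            X[:, :3] = rng.normal(0, sd, size=(300, 3))
            m = SetupUncertaintyModel(
                r_grid=(0.0, 10.0), n_sim=2000, n_boot=100,
                random_state=200 + i,
            ).fit(X, groups=np.arange(300) % 60)
            c = m.percentile_curve()
            hits += c.lower[0] <= true_q <= c.upper[0]
        assert hits >= int(0.8 * n_rep)

    def test_empty_timepoint_is_informative(self, zero_cohort):
        with pytest.raises(ValueError, match="no records"):
            percentile_curve(zero_cohort, "orthogonal2D")


class TestRepresentativeErrorTable:
    def test_carries_metadata_and_is_seeded(self, small_cohort):
        cohort, _ = small_cohort
        t1 = representative_error_table(cohort, "posttreatment",
                                        n_draws=200, random_state=3)
        t2 = representative_error_table(cohort, "posttreatment",
                                        n_draws=200, random_state=3)
        assert (t1["value_mm"] == t2["value_mm"]).all()
        assert set(t1.columns) == {
            "patient_id", "week", "anesthesia", "timepoint", "value_mm"
        }
        assert (t1["value_mm"] >= 0).all()
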