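import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import natri
from natri.errors import DomainError, IdentifiabilityError, ValidationError
from natri.usual import fit_amount_model, usual_intake_per_person
from .conftest import make_cohort, NOISE_FREE_KW


class TestBoxcox:
    @pytest.mark.parametrize("lam", [0.0, 0.25, 0.5, 1.0])
    def test_fixed_point_at_one(self, lam):
        assert natri.boxcox(1.0, lam) == pytest.approx(0.0)

    def test_log_case(self):
        assert natri.boxcox(np.e, 0.0) == pytest.approx(1.0)

    def test_half_power(self):
        assert natri.boxcox(9.0, 0.5) == pytest.approx(4.0)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            natri.boxcox(0.0, 0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(x=st.floats(0.01, 1e4), d=st.floats(0.01, 10),
           lam=st.sampled_from([0.0, 0.1, 0.5, 1.0]))
    def test_strictly_increasing(self, x, d, lam):
        assert natri.boxcox(x + d, lam) > natri.boxcox(x, lam)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(x=st.floats(0.01, 1e4), lam=st.sampled_from([0.0, 0.1, 0.5, 1.0]))
    def test_inverse(self, x, lam):
        assert natri.inv_boxcox(natri.boxcox(x, lam), lam) == pytest.approx(x, rel=1e-9)


class TestFit:
    def test_parameter_recovery(self, recovery_cohort):
        """lambda=0, sigma_b=0.25, sigma_w=0.35 planted; recovered within band."""
        _, demo, recalls, _ = recovery_cohort
        m = fit_amount_model(recalls, demo)
        assert abs(m.lam - 0.0) <= 0.15
        assert abs(m.sigma2_between / 0.25 ** 2 - 1) < 0.20
        assert abs(m.sigma2_within / 0.35 ** 2 - 1) < 0.20

    def test_noise_free_degenerate(self, noise_free_cohort):
        _, demo, recalls, _ = noise_free_cohort
        m = fit_amount_model(recalls, demo, lam=0.0)
        assert m.sigma2_within < 1e-6
        ui = usual_intake_per_person(m)
        tot = recalls.groupby(["person_id", "day"])["sodium_mg"].sum() \
                     .groupby("person_id").mean()
        assert np.allclose(ui, tot.reindex(ui.index), rtol=1e-9)

    def test_weight_rescaling_invariance(self, small_cohort):
        _, demo, recalls, _ = small_cohort
        m1 = fit_amount_model(recalls, demo)
        demo2 = demo.copy()
        demo2["weight"] = demo2["weight"] * 17.0
        m2 = fit_amount_model(recalls, demo2)
        assert m1.lam == m2.lam
        assert m1.sigma2_between == pytest.approx(m2.sigma2_between, rel=1e-10)
        assert m1.sigma2_within == pytest.approx(m2.sigma2_within, rel=1e-10)
        np.testing.assert_allclose(m1.beta, m2.beta, rtol=1e-8)

    def test_duplication_with_halved_weights(self, small_cohort):
        """Duplicating every person at half weight leaves estimates unchanged."""
        _, demo, recalls, _ = small_cohort
        m1 = fit_amount_model(recalls, demo)
        demo2 = demo.copy()
        demo2["person_id"] = demo2["person_id"] + "_dup"
        demo_dup = pd.concat([demo, demo2], ignore_index=True)
        demo_dup["weight"] = demo_dup["weight"] / 2
        rec2 = recalls.copy()
        rec2["person_id"] = rec2["person_id"] + "_dup"
        rec_dup = pd.concat([recalls, rec2], ignore_index=True)
        m2 = fit_amount_model(rec_dup, demo_dup)
        assert m1.lam == m2.lam
        assert m1.sigma2_between == pytest.approx(m2.sigma2_between, rel=1e-8)
        assert m1.sigma2_within == pytest.approx(m2.sigma2_within, rel=1e-8)
        np.testing.assert_allclose(m1.beta, m2.beta, rtol=1e-6)

    def test_single_day_identifiability_error(self, small_cohort):
        _, demo, recalls, _ = small_cohort
        with pytest.raises(IdentifiabilityError):
            fit_amount_model(recalls[recalls.day == 1], demo)

    def test_nonpositive_total_rejected(self, small_cohort):
        _, demo, recalls, _ = small_cohort
        bad = recalls.copy()
        bad.loc[bad.index[:1], "sodium_mg"] = 0.0
        pid = bad.iloc[0]["person_id"]
        bad.loc[bad.person_id == pid, "sodium_mg"] = 0.0
        with pytest.raises(DomainError):
            fit_amount_model(bad, demo)

    def test_quadrature_config_error(self, small_cohort):
        _, demo, recalls, _ = small_cohort
        with pytest.raises(ValidationError):
            fit_amount_model(recalls, demo, n_quadrature=2)


class TestUsualIntake:
    def test_lognormal_closed_form(self, recovery_cohort):
        """At lambda=0 the quadrature must equal the lognormal closed form
        exp(mu + (v_post + s_w^2)/2)."""
        _, demo, recalls, _ = recovery_cohort
        m = fit_amount_model(recalls, demo, lam=0.0)
        ui = usual_intake_per_person(m)
        closed = np.exp(m.persons["mu_ref"].to_numpy()
                        + (m.persons["post_var"].to_numpy()
                           + m.sigma2_within) / 2)
        np.testing.assert_allclose(ui, closed, rtol=1e-6)
        # day-noise-only prediction matches exp(mu + s_w^2/2)
        np.testing.assert_allclose(
            m.usual_of_mu(m.persons["mu_ref"].to_numpy()),
            np.exp(m.persons["mu_ref"].to_numpy() + m.sigma2_within / 2),
            rtol=1e-6)

    def test_quadrature_convergence(self, small_cohort):
        _, demo, recalls, _ = small_cohort
        m9 = fit_amount_model(recalls, demo, lam=0.3, n_quadrature=9)
        m41 = fit_amount_model(recalls, demo, lam=0.3, n_quadrature=41)
        np.testing.assert_allclose(usual_intake_per_person(m9),
                                   usual_intake_per_person(m41), rtol=1e-4)

    def test_monotone_in_mu(self, small_cohort):
        _, demo, recalls, _ = small_cohort
        m = fit_amount_model(recalls, demo)
        mu = np.linspace(m.persons.mu_ref.min(), m.persons.mu_ref.max(), 50)
        u = m.usual_of_mu(mu)
        assert (np.diff(u) > 0).all()

    def test_strictly_positive(self, recovery_cohort):
        _, demo, recalls, _ = recovery_cohort
        m = fit_amount_model(recalls, demo)
        assert (usual_intake_per_person(m) > 0).all()


class TestSubgroupSummary:
    def test_equal_weights_single_domain(self, small_cohort):
        _, demo, recalls, _ = small_cohort
        demo_eq = demo.copy()
        demo_eq["weight"] = 1.0
        res = natri.subgroup_summary(recalls, demo_eq, by=("cycle",), n_boot=0)
        m = fit_amount_model(recalls, demo_eq)
        ui = usual_intake_per_person(m)
        assert res["mean"].iloc[0] == pytest.approx(float(ui.mean()), rel=1e-9)

    def test_threshold_nesting(self, small_cohort):
        _, demo, recalls, _ = small_cohort
        res = natri.subgroup_summary(recalls, demo, n_boot=0)
        assert (res.prop_below_1500 <= res.prop_below_2300 + 1e-12).all()
        assert res.prop_below_1500.between(0, 1).all()

    def test_planted_ethnicity_ordering(self):
        """Configured White > Black > Hispanic means are recovered at n=2000."""
        base = {"Non-Hispanic White": 4000, "Non-Hispanic Black": 3600,
                "Other Hispanic": 3300, "Mexican American": 3200, "Other": 3000}
        sb, sw = 0.25, 0.35
        means = {(a, g, e): float(np.log(b) - (sb**2 + sw**2) / 2)
                 for e, b in base.items()
                 for a in natri.io.AGE_GROUPS for g in natri.io.GENDERS}
        _, demo, recalls, _ = make_cohort(
            n_persons=2000, seed=13, subgroup_log_means=means,
            beta_weekend=0.0, beta_sequence=0.0)
        res = natri.subgroup_summary(recalls, demo, by=("ethnicity",), n_boot=0)
        got = res.set_index("ethnicity")["mean"]
        assert got["Non-Hispanic White"] > got["Non-Hispanic Black"]
        assert got["Non-Hispanic Black"] > got["Other Hispanic"]
        assert got["Non-Hispanic Black"] > got["Mexican American"]

    def test_bootstrap_se_present_and_positive(self, small_cohort):
        _, demo, recalls, _ = small_cohort
        res = natri.subgroup_summary(recalls, demo, by=("gender",),
                                     n_boot=30, seed=4)
        assert (res.se > 0).all()

    def test_weight_scaling_leaves_estimates_unchanged(self, small_cohort):
        _, demo, recalls, _ = small_cohort
        r1 = natri.subgroup_summary(recalls, demo, by=("gender",), n_boot=0)
        demo2 = demo.copy()
        demo2["weight"] = demo2["weight"] * 1000
        r2 = natri.subgroup_summary(recalls, demo2, by=("gender",), n_boot=0)
        pd.testing.assert_frame_equal(r1.drop(columns="se"), r2.drop(columns="se"))
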