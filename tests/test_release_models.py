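"""Power-law release models: evaluation, fitting, mechanism classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lai_ivivc as L
from lai_ivivc.release_models import PowerLawPhase, CompositeReleaseModel


def make_f1_composite():
    """Celecoxib formulation-1 style triphasic model (fraction scale)."""
    return CompositeReleaseModel(phases=(
        PowerLawPhase(K=0.0485, n=0.471, t_start=0.0, t_end=24.0),
        PowerLawPhase(K=0.0125, n=0.616, t_start=0.0, t_end=312.0),
        PowerLawPhase(K=0.30e-3, n=1.22, t_start=312.0, t_end=2568.0,
                      anchor=312.0),
    ))


class TestEvalPowerLaw:
    @pytest.mark.parametrize("K,n,t,expected", [
        (0.207, 0.406, 1.0, 0.207),          # t=1 returns K
        (0.0652, 0.406, 161.0, 0.5131200),   # slow-release fit at its t50
    ])
    def test_values(self, K, n, t, expected):
        ph = PowerLawPhase(K=K, n=n, t_start=0.0, t_end=1e4)
        assert L.eval_power_law(ph, t) == pytest.approx(expected, rel=1e-6)

    def test_zero_at_anchor_and_frozen_after_window(self):
        ph = PowerLawPhase(K=0.1, n=0.5, t_start=10.0, t_end=100.0, anchor=10.0)
        assert L.eval_power_law(ph, 10.0) == 0.0
        assert L.eval_power_law(ph, 5.0) == 0.0
        frozen = L.eval_power_law(ph, 100.0)
        assert L.eval_power_law(ph, 500.0) == frozen

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PowerLawPhase(K=-1.0, n=0.5)
        with pytest.raises(ValueError):
            PowerLawPhase(K=0.1, n=0.0)
        with pytest.raises(ValueError):
            PowerLawPhase(K=0.1, n=0.5, t_start=10, t_end=5)
        with pytest.raises(ValueError):
            PowerLawPhase(K=0.1, n=0.5, t_start=5, t_end=10, anchor=7)


class TestEvalComposite:
    def test_triphasic_value(self):
        # burst frozen at 24 h + second phase frozen at 312 h + erosion term
        model = make_f1_composite()
        assert L.eval_composite(model, 456.0) == pytest.approx(0.775445, abs=1e-4)

    def test_zero_and_cap(self):
        model = make_f1_composite()
        assert L.eval_composite(model, 0.0) == 0.0
        assert L.eval_composite(model, 2568.0) == 1.0

    def test_cap_time_matches_uncapped_crossing(self):
        model = make_f1_composite()
        ct = model.cap_time()
        assert model.evaluate_uncapped(ct) == pytest.approx(1.0, abs=1e-8)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        K1=st.floats(1e-4, 0.3), n1=st.floats(0.1, 0.9),
        K2=st.floats(1e-6, 0.05), n2=st.floats(0.2, 1.0),
        K3=st.floats(1e-6, 5e-3), n3=st.floats(1.0, 2.0),
        b1=st.floats(10.0, 50.0), b2=st.floats(100.0, 600.0),
    )
    def test_monotone_and_bounded(self, K1, n1, K2, n2, K3, n3, b1, b2):
        model = CompositeReleaseModel(phases=(
            PowerLawPhase(K=K1, n=n1, t_start=0.0, t_end=b1),
            PowerLawPhase(K=K2, n=n2, t_start=0.0, t_end=b2),
            PowerLawPhase(K=K3, n=n3, t_start=b2, t_end=3000.0, anchor=b2),
        ))
        t = np.linspace(0.0, 3000.0, 400)
        y = model.evaluate(t)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all((y >= 0.0) & (y <= 1.0))


class TestAlternativeForms:
    def test_higuchi_is_square_root_power_law(self):
        h = L.higuchi(K=0.05)
        assert h.n == 0.5
        assert h.contribution(4.0) == pytest.approx(0.1)

    def test_peppas_sahlin_sum_of_terms(self):
        m = L.PeppasSahlinModel(K1=0.05, K2=0.002, n1=0.45, n2=0.9)
        t = 10.0
        assert m.evaluate(t) == pytest.approx(0.05 * t ** 0.45
                                              + 0.002 * t ** 0.9)
        with pytest.raises(ValueError):
            L.PeppasSahlinModel(K1=-0.1, K2=0.0, n1=0.5, n2=1.0)


class TestFitPowerLaw:
    def test_noise_free_identity(self):
        t = np.geomspace(1.0, 100.0, 25)
        y = 0.1 * t ** 0.45
        fit = L.fit_power_law((t, y))
        assert fit.model.K == pytest.approx(0.1, rel=1e-6)
        assert fit.model.n == pytest.approx(0.45, rel=1e-6)

    def test_fixed_n_matches_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        t = np.geomspace(1.0, 200.0, 30)
        y = 0.12 * t ** 0.38 * rng.lognormal(0.0, 0.05, t.size)
        y = np.clip(y, 0.0, 0.85)
        n_fix = 0.406
        fit = L.fit_power_law((t, y), fixed_n=n_fix)
        grid = np.linspace(0.01, 0.5, 20001)
        sse = [np.sum((K * t ** n_fix - y) ** 2) for K in grid]
        K_star = grid[int(np.argmin(sse))]
        assert fit.model.K == pytest.approx(K_star, abs=grid[1] - grid[0])

    def test_refit_recovers_published_rate_constant(self, fx, ivr_schedule_long):
        # noise-free mean profile from the slow-release truth, refit at the
        # shared average exponent
        truth = fx.release_model("celecoxib", "F1")
        y = truth.evaluate(ivr_schedule_long)
        fit = L.fit_power_law((ivr_schedule_long, y), window=(0.0, 312.0),
                              fixed_n=0.406)
        assert fit.model.K == pytest.approx(0.0652, abs=1e-6)

    def test_fixed_n_sse_not_below_free_fit(self):
        rng = np.random.default_rng(5)
        t = np.geomspace(1.0, 300.0, 25)
        y = np.clip(0.08 * t ** 0.5 * rng.lognormal(0, 0.08, t.size), 0, 0.85)
        free = L.fit_power_law((t, y))
        fixed = L.fit_power_law((t, y), fixed_n=0.406)
        assert fixed.sse >= free.sse - 1e-12

    def test_degenerate_window_flagged(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.full(4, 0.3)
        fit = L.fit_power_law((t, y))
        assert fit.model.K == 0.0
        assert fit.warnings


class TestFitComposite:
    def test_triphasic_self_consistency(self, fx, ivr_schedule_long):
        truth = fx.in_vitro_model("F3")
        y = truth.evaluate(ivr_schedule_long)
        fit = L.fit_composite((ivr_schedule_long, y), breakpoints=[24.0, 312.0])
        want = [(0.0308, 0.471), (9.12e-3, 0.616), (0.45e-3, 1.22)]
        for ph, (K, n) in zip(fit.model.phases, want):
            assert ph.K == pytest.approx(K, rel=1e-4)
            assert ph.n == pytest.approx(n, rel=1e-4)

    def test_biphasic_profile_has_no_third_phase(self, fx, ivr_schedule_long):
        truth = fx.in_vitro_model("F2")
        y = truth.evaluate(ivr_schedule_long)
        fit = L.fit_composite((ivr_schedule_long, y), breakpoints=[24.0])
        assert len(fit.model.phases) == 2

    def test_tied_exponent_shared_across_profiles(self, fx, ivr_schedule_long):
        rng = np.random.default_rng(3)
        profiles = []
        for form in ("F1", "F2", "F3", "F4"):
            y = fx.in_vitro_model(form).evaluate(ivr_schedule_long)
            y = np.clip(y * rng.lognormal(0, 0.02, y.size), 0, None)
            profiles.append((ivr_schedule_long, y))
        fits = L.fit_composite(profiles, breakpoints=[24.0], ties={"n": True})
        n_burst = {round(f.model.phases[0].n, 12) for f in fits}
        n_second = {round(f.model.phases[1].n, 12) for f in fits}
        assert len(n_burst) == 1 and len(n_second) == 1


class TestGoodnessOfFit:
    def test_perfect_fit_and_constant_fit(self):
        t = np.array([1.0, 5.0, 20.0, 50.0, 100.0])
        model = PowerLawPhase(K=0.05, n=0.5, t_start=0.0, t_end=200.0)
        y = model.contribution(t)
        assert L.goodness_of_fit_pearson(model, (t, y)) == pytest.approx(1.0)
        flat = PowerLawPhase(K=0.0, n=0.5, t_start=0.0, t_end=200.0)
        assert np.isnan(L.goodness_of_fit_pearson(flat, (t, y)))

    def test_five_point_example_matches_textbook_formula(self):
        t = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        model = PowerLawPhase(K=0.1, n=0.5, t_start=0.0, t_end=100.0)
        obs = np.array([0.12, 0.13, 0.22, 0.26, 0.42])
        yhat = model.contribution(t)
        mx, my = yhat.mean(), obs.mean()
        r_hand = (np.sum((yhat - mx) * (obs - my))
                  / np.sqrt(np.sum((yhat - mx) ** 2) * np.sum((obs - my) ** 2)))
        assert L.goodness_of_fit_pearson(model, (t, obs)) == pytest.approx(r_hand)

    def test_truncated_at_plateau_onset(self):
        # once the fitted curve exceeds 0.95 later points are ignored
        t = np.arange(1.0, 40.0)
        model = PowerLawPhase(K=0.2, n=0.5, t_start=0.0, t_end=100.0)
        y = np.minimum(model.contribution(t), 1.0)
        r = L.goodness_of_fit_pearson(model, (t, y))
        assert r == pytest.approx(1.0, abs=1e-9)


class TestMechanism:
    @pytest.mark.parametrize("n,label", [
        (0.406, "pseudo-Fickian"),
        (0.5, "pseudo-Fickian"),
        (0.75, "anomalous"),
        (1.0, "case II"),
        (1.22, "super-case II"),
    ])
    def test_labels(self, n, label):
        assert L.classify_mechanism(n) == label

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            L.classify_mechanism(0.0)


class TestSolubilityRegression:
    def test_two_points_exact_line(self):
        slope, intercept, r2 = L.regress_K_on_solubility([0.1, 0.3], [1.0, 3.0])
        assert slope == pytest.approx(0.1)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_constant_K_gives_zero_slope(self):
        slope, _, _ = L.regress_K_on_solubility([0.2, 0.2, 0.2], [1.0, 2.0, 5.0])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_published_rate_constants_increase_with_solubility(self, fx):
        # in the low-solubility regime (felbinac, indomethacin, celecoxib) K
        # rises with solubility in every formulation group
        drugs = ["celecoxib", "indomethacin", "felbinac"]
        for form in ("F1", "F2", "F3", "F4"):
            Ks = [fx["kp_fits"][d][form]["main"].K for d in drugs]
            sols = [fx["solubility"][d] for d in drugs]
            slope, _, _ = L.regress_K_on_solubility(Ks, sols)
            assert slope > 0
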