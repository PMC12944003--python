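"""Withdrawal-corrected release profiles and dissolution statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lai_ivivc as L
from lai_ivivc.synthetic_data import IVRDesign


def raw_table(times, conc, vessel="V1"):
    return pd.DataFrame({"vessel_id": vessel, "time_h": times,
                         "conc_mg_per_ml": conc})


DESIGN = IVRDesign(schedule=(24.0, 48.0), noise_cv=0.0)  # 3 mg dose, 50/4 mL


class TestCumulativeRelease:
    def test_hand_bookkeeping(self):
        # dose 3 mg (0.3 g at 10 mg/g): masses 0.5 and 0.64 mg
        prof = L.cumulative_release(
            raw_table([24.0, 48.0], [0.010, 0.012]), DESIGN)
        assert prof.fractions[0] == pytest.approx([0.5 / 3, 0.64 / 3])

    def test_all_zero_concentrations(self):
        prof = L.cumulative_release(raw_table([24.0, 48.0], [0.0, 0.0]), DESIGN)
        assert np.all(prof.fractions == 0.0)

    def test_single_time_point_no_correction(self):
        design = IVRDesign(schedule=(24.0,), noise_cv=0.0)
        prof = L.cumulative_release(raw_table([24.0], [0.010]), design)
        assert prof.fractions[0, 0] == pytest.approx(0.010 * 50 / 3)

    def test_vessel_with_missing_point_excluded(self):
        df = pd.concat([raw_table([24.0, 48.0], [0.01, 0.012], "V1"),
                        raw_table([24.0], [0.01], "V2")])
        prof = L.cumulative_release(df, DESIGN)
        assert prof.n_vessels == 1
        assert any("V2" in w for w in prof.warnings)

    def test_split_withdrawal_invariance(self, fx):
        """Splitting one withdrawal into two half-volume withdrawals taken
        back-to-back leaves the recovered cumulative fractions unchanged."""
        truth = fx.release_model("felbinac", "F1")
        times = np.array([24.0, 96.0, 240.0])
        eps = 1e-9

        def measured(schedule, Vs, V=50.0, dose=3.0):
            F = truth.evaluate(np.asarray(schedule))
            conc, removed = [], 0.0
            for f in F:
                c = (f * dose - removed) / V
                conc.append(c)
                removed += c * Vs
            return np.array(conc)

        whole = L.cumulative_release(
            raw_table(times, measured(times, 4.0)),
            IVRDesign(schedule=tuple(times), noise_cv=0.0))
        split_times = np.sort(np.concatenate([times, times + eps]))
        split = L.cumulative_release(
            raw_table(split_times, measured(split_times, 2.0)),
            IVRDesign(schedule=tuple(split_times), withdrawal_volume=2.0,
                      noise_cv=0.0))
        np.testing.assert_allclose(split.fractions[0, 1::2],
                                   whole.fractions[0], rtol=1e-7)


class TestTimeToFraction:
    def prof(self, times, fracs):
        return L.ReleaseProfile(times=np.asarray(times, float),
                                fractions=np.asarray(fracs, float),
                                dose_mg=3.0)

    def test_midpoint_interpolation(self):
        res = L.time_to_fraction(self.prof([24, 48], [[0.4, 0.6]]), 0.5)
        assert res.per_vessel[0] == pytest.approx(36.0)

    def test_exact_observed_value(self):
        res = L.time_to_fraction(self.prof([24, 48], [[0.5, 0.8]]), 0.5)
        assert res.per_vessel[0] == 24.0

    def test_censored_rendering(self):
        res = L.time_to_fraction(self.prof([24, 480], [[0.1, 0.4]]), 0.8)
        assert res.any_censored
        assert str(res) == ">480"

    def test_matches_root_of_composite(self, fx):
        truth = fx.in_vitro_model("F1")
        t = np.arange(1.0, 700.0, 1.0)
        prof = self.prof(t, [truth.evaluate(t)])
        res = L.time_to_fraction(prof, 0.5)
        root = truth.time_to_fraction(0.5)
        assert res.per_vessel[0] == pytest.approx(root, abs=2.0)


class TestSimilarityFactors:
    def test_f1_cases(self):
        r = np.array([20.0, 40.0, 60.0])
        assert L.f1_difference(r, r) == 0.0
        assert L.f1_difference(np.full(5, 50.0), np.full(5, 40.0)) == pytest.approx(20.0)
        assert L.f1_difference(r, r - 10.0) == pytest.approx(25.0)

    def test_f2_closed_forms(self):
        r = np.linspace(10, 90, 9)
        assert L.f2_similarity(r, r) == pytest.approx(100.0)
        # uniform 10-point gap: 50*log10(100/sqrt(101))
        assert L.f2_similarity(r, r - 10.0) == pytest.approx(49.8920, abs=0.01)
        # uniform 2-point gap: 50*log10(100/sqrt(5))
        assert L.f2_similarity(r, r - 2.0) == pytest.approx(82.5257, abs=0.01)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            L.f2_similarity(np.ones(3), np.ones(4))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(0.0, 100.0), min_size=1, max_size=12))
    def test_identity_properties(self, values):
        r = np.asarray(values)
        assert L.f2_similarity(r, r) == pytest.approx(100.0)
        if r.sum() > 0:
            assert L.f1_difference(r, r) == 0.0


class TestWelch:
    def test_identical_groups(self):
        t, df, p = L.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        t, _, p = L.welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_textbook_pair_matches_direct_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 4.0, 5.0, 6.0])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
        t, df, p = L.welch_t_test(a, b)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        t2, _, p2 = L.welch_t_test(b, a)
        assert t2 == pytest.approx(-t)
        assert p2 == pytest.approx(p)
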