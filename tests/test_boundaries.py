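"""Critical boundaries, the universal three-body threshold, and regime cases."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from promothermo import (
    TwoActivatorSystem,
    boundary_curve,
    classify_regime,
    critical_xp_equal_activators,
    critical_xp_vs_energy,
    limiting_sign_statistic,
    minimal_universal_three_body_factor,
    saturated_sign_statistic,
    sign_scan_oracle,
    synergy_difference,
    synergy_sign_statistic,
    three_body_hyperbola,
    two_body_hyperbola,
)


def saturated_D(x_p: float, w: float) -> float:
    """Equal activators, neutral omegas, joint saturation (analytic oracle)."""
    r_ab = x_p * w * w
    r_single = x_p * w
    return r_ab / (1 + r_ab) - 2 * r_single / (1 + r_single)


class TestSignStatistic:
    def test_sign_matches_difference_measure(self, rng):
        for _ in range(200):
            x_p, x_a, x_b = np.exp(rng.uniform(np.log(1e-3), np.log(1e3), 3))
            w_a, w_b = np.exp(rng.uniform(np.log(1e-2), np.log(1e2), 2))
            s = TwoActivatorSystem(x_p, x_a, x_b, w_a, w_b)
            D = synergy_difference(s).D
            g = synergy_sign_statistic(s)
            assert np.sign(g) == np.sign(D) or abs(D) < 1e-15

    def test_rejected_outside_neutral_omegas(self):
        with pytest.raises(ValueError, match="omega"):
            synergy_sign_statistic(TwoActivatorSystem(0.1, 1, 1, 2, 2, omega3=2.0))

    def test_zero_on_saturated_boundary(self):
        for w in (2.5, 3.0, 4.0, 8.0):
            x_p = critical_xp_equal_activators(w)
            assert saturated_sign_statistic(w, w, x_p) == pytest.approx(0.0, abs=1e-10)

    def test_sign_flips_across_boundary_at_large_doses(self):
        w = 4.0
        x_crit = critical_xp_equal_activators(w)  # 1/8
        above = TwoActivatorSystem(x_crit * 1.5, 1e8, 1e8, w, w)
        below = TwoActivatorSystem(x_crit * 0.5, 1e8, 1e8, w, w)
        assert synergy_sign_statistic(above) < 0 and synergy_difference(above).D < 0
        assert synergy_sign_statistic(below) > 0 and synergy_difference(below).D > 0


class TestEqualActivatorBoundary:
    def test_onset_at_w_two(self):
        assert critical_xp_equal_activators(2.0) == 0.0
        assert critical_xp_equal_activators(1.5) is None

    def test_peak_at_w_four(self):
        w_grid = np.linspace(2.0, 50.0, 2000)
        values = np.array([critical_xp_equal_activators(w) for w in w_grid])
        assert values.max() == pytest.approx(0.125, abs=1e-4)
        assert w_grid[values.argmax()] == pytest.approx(4.0, abs=0.05)
        assert critical_xp_equal_activators(4.0) == pytest.approx(1 / 8, abs=1e-15)

    def test_unimodal_and_decaying(self):
        w_grid = np.linspace(2.0, 1e4, 5000)
        values = np.array([critical_xp_equal_activators(w) for w in w_grid])
        diffs = np.sign(np.diff(values))
        flips = np.count_nonzero(np.diff(diffs[diffs != 0]))
        assert flips == 1  # rises then decays, single interior maximum
        assert critical_xp_equal_activators(1e9) == pytest.approx(0.0, abs=1e-8)
        assert (values < 0.5).all()

    def test_nonpositive_w_rejected(self):
        with pytest.raises(ValueError):
            critical_xp_equal_activators(0.0)

    @pytest.mark.parametrize("w", [2.25, 2.5, 3.0, 4.0, 6.0, 10.0])
    def test_matches_bisection_root_of_saturated_D(self, w):
        root = brentq(lambda x_p: saturated_D(x_p, w), 1e-12, 0.5, xtol=1e-14)
        assert critical_xp_equal_activators(w) == pytest.approx(root, abs=1e-8)

    def test_reentrance_in_w_at_fixed_xp(self):
        # for x_P inside (0, 1/8) the saturated D over w is -, +, - with two roots
        x_p = 0.05
        w_grid = np.logspace(0, 3, 4000)
        signs = np.sign([saturated_D(x_p, w) for w in w_grid])
        changes = np.nonzero(np.diff(signs))[0]
        assert len(changes) == 2
        assert signs[0] < 0 and signs[-1] < 0
        assert signs[changes[0] + 1] > 0


class TestEnergyParameterization:
    def test_change_of_variables(self):
        assert critical_xp_vs_energy(math.log(2.0)) == pytest.approx(0.0, abs=1e-15)
        assert critical_xp_vs_energy(math.log(4.0)) == pytest.approx(0.125, abs=1e-15)

    def test_consistent_with_w_parameterization(self):
        for g in np.linspace(math.log(2.0), 5.0, 50):
            assert critical_xp_vs_energy(g) == critical_xp_equal_activators(math.exp(g))


class TestHyperbolae:
    def test_two_body_diagonal_crossing_at_two(self):
        assert two_body_hyperbola(2.0) == pytest.approx(2.0, abs=1e-15)
        root = brentq(lambda w: limiting_sign_statistic(w, w, 1.0), 1.1, 10.0)
        assert root == pytest.approx(2.0, abs=1e-10)

    def test_two_body_asymptote(self):
        assert two_body_hyperbola(1e9) == pytest.approx(1.0, rel=1e-8)
        with pytest.raises(ValueError, match="w_A > 1"):
            two_body_hyperbola(1.0)

    def test_point_above_curve_is_synergistic_in_full_model(self):
        w_a = 3.0
        w_b = two_body_hyperbola(w_a) * 1.3  # above the curve
        s = TwoActivatorSystem(1e-4, 1e6, 1e6, w_a, w_b)
        assert synergy_difference(s).D > 0
        below = TwoActivatorSystem(1e-4, 1e6, 1e6, w_a, two_body_hyperbola(w_a) * 0.7)
        assert synergy_difference(below).D < 0

    def test_three_body_reduces_to_two_body_at_unit_factor(self):
        for w_a in np.logspace(0.01, 2, 40):
            if w_a <= 1.0:
                continue
            assert abs(three_body_hyperbola(w_a, 1.0) - two_body_hyperbola(w_a)) <= 1e-12

    def test_three_body_diagonal_crossing(self):
        omega3 = 4.0
        root = brentq(lambda w: limiting_sign_statistic(w, w, omega3), 1e-3, 10.0)
        # hyperbola crosses the diagonal where w = 2/omega3
        assert root == pytest.approx(2.0 / omega3, abs=1e-10)
        assert three_body_hyperbola(root, omega3) == pytest.approx(root, rel=1e-10)

    def test_asymptotes_move_toward_axes(self):
        # asymptote sits at w_A = 1/omega3: larger omega3, closer to the axis
        with pytest.raises(ValueError, match="asymptote"):
            three_body_hyperbola(1.0 / 2.0, 2.0)
        assert three_body_hyperbola(0.2, 10.0) > 0  # already valid for omega3 = 10
        for w_a in (0.6, 1.0, 3.0):
            assert three_body_hyperbola(w_a, 10.0) < three_body_hyperbola(w_a, 2.0)


class TestUniversalThreeBodyThreshold:
    def test_threshold_is_two(self):
        assert minimal_universal_three_body_factor() == pytest.approx(2.0, abs=1e-3)

    def test_worst_case_at_weakest_activators(self):
        threshold = minimal_universal_three_body_factor()
        grid = np.logspace(math.log10(1.0 + 1e-4), 2, 200)
        h = limiting_sign_statistic(grid[:, None], grid[None, :], threshold)
        i, j = np.unravel_index(np.argmin(h), h.shape)
        assert i == 0 and j == 0  # minimum at w_A = w_B -> 1+

    def test_margin_above_threshold(self):
        threshold = minimal_universal_three_body_factor()
        grid = np.logspace(math.log10(1.0 + 1e-4), 2, 200)
        h = limiting_sign_statistic(grid[:, None], grid[None, :], threshold * 1.01)
        assert (h > 0).all()


class TestClassifyRegime:
    def test_low_tf_concentrations(self):
        s = TwoActivatorSystem(0.3, 1e-4, 1e-4, 3.0, 3.0)
        label = classify_regime(s)
        assert (label.case_id, label.predicted_sign) == ("1", "negative")

    def test_weak_activators_negative_even_with_tf_tf_coupling(self):
        s = TwoActivatorSystem(0.1, 10.0, 10.0, 1.2, 1.2, omega_AB=50.0)
        label = classify_regime(s)
        assert (label.case_id, label.predicted_sign) == ("2", "negative")
        # the bound w_A w_B omega3 <= 2 really forces D < 0 at these parameters
        assert synergy_difference(s).D < 0

    def test_high_rnap_concentration(self):
        s = TwoActivatorSystem(0.8, 1.0, 1.0, 3.0, 4.0)
        label = classify_regime(s)
        assert (label.case_id, label.predicted_sign) == ("3", "negative")

    def test_weak_activation_products(self):
        s = TwoActivatorSystem(0.1, 0.5, 0.5, 1.8, 1.8)
        label = classify_regime(s)
        assert (label.case_id, label.predicted_sign) == ("4", "negative")

    def test_strong_three_body(self):
        s = TwoActivatorSystem(1e-3, 1e3, 1e3, 5.0, 5.0, omega3=3.0)
        label = classify_regime(s)
        assert (label.case_id, label.predicted_sign) == ("7b", "positive")
        assert synergy_difference(s).D > 0

    def test_moderate_three_body_sign_from_hyperbola(self):
        s = TwoActivatorSystem(1e-3, 1e3, 1e3, 1.3, 1.3, omega3=1.5)
        label = classify_regime(s)
        assert label.case_id == "7a"
        assert label.predicted_sign == ("positive" if 1.5 * 1.3 * 1.3 > 2.6 else "negative")

    def test_nonlinearity_with_tf_tf_coupling(self):
        s = TwoActivatorSystem(1e-3, 1e3, 1e3, 5.0, 5.0, omega_AB=4.0)
        label = classify_regime(s)
        assert (label.case_id, label.predicted_sign) == ("6", "positive")

    def test_equal_activator_case_sign_from_boundary(self):
        below = TwoActivatorSystem(0.05, 1e3, 1e3, 4.0, 4.0)
        above = TwoActivatorSystem(0.3, 1e3, 1e3, 4.0, 4.0)
        assert classify_regime(below).case_id == "5b"
        assert classify_regime(below).predicted_sign == "positive"
        assert classify_regime(above).predicted_sign == "negative"

    def test_unequal_activator_case(self):
        s = TwoActivatorSystem(0.3, 1e3, 1e3, 3.0, 60.0)
        label = classify_regime(s)
        assert label.case_id == "5a"
        expected = np.sign(saturated_sign_statistic(3.0, 60.0, 0.3))
        assert label.predicted_sign == ("positive" if expected > 0 else "negative")

    def test_repressor_rejected(self):
        with pytest.raises(ValueError, match="activators"):
            classify_regime(TwoActivatorSystem(0.1, 1.0, 1.0, 0.5, 3.0))


class TestSignScanOracle:
    def test_all_neutral_factors_scan_negative(self):
        template = TwoActivatorSystem(0.4, 1.0, 1.0)
        table = sign_scan_oracle(
            template, {"x_A": np.logspace(-2, 2, 9), "x_B": np.logspace(-2, 2, 9)}
        )
        assert (table["sign"] == -1).all()

    def test_symmetric_template_scan_is_symmetric(self):
        template = TwoActivatorSystem(0.05, 1.0, 1.0, 4.0, 4.0)
        grid = np.logspace(-2, 2, 7)
        table = sign_scan_oracle(template, {"x_A": grid, "x_B": grid})
        D = table["D"].to_numpy().reshape(7, 7)
        assert np.allclose(D, D.T, atol=1e-14)

    def test_boundary_agrees_with_scan_within_one_cell(self):
        # the saturated equal-activator boundary must sit within one x_P grid
        # cell of the sign flip observed in a brute-force dose scan
        xp_grid = np.linspace(0.01, 0.2, 39)
        for w in (3.0, 4.0, 6.0):
            template = TwoActivatorSystem(0.1, 1e8, 1e8, w, w)
            table = sign_scan_oracle(template, {"x_P": xp_grid})
            signs = table["sign"].to_numpy()
            flip = np.nonzero(np.diff(signs))[0]
            assert len(flip) == 1
            lo, hi = xp_grid[flip[0]], xp_grid[flip[0] + 1]
            assert lo <= critical_xp_equal_activators(w) <= hi

    def test_grid_cap_enforced(self):
        template = TwoActivatorSystem(0.1, 1.0, 1.0)
        with pytest.raises(ValueError, match="cap"):
            sign_scan_oracle(template, {"x_A": np.ones(2000), "x_B": np.ones(2000)})


class TestBoundaryCurveSampling:
    def test_eq21_samples(self):
        curve = boundary_curve("eq21", 1.0, 10.0, 91)
        assert curve.samples["coordinate"].min() >= 2.0  # no boundary below w = 2
        assert curve.samples["critical_value"].max() == pytest.approx(0.125, abs=1e-3)

    def test_eq24_respects_asymptote(self):
        curve = boundary_curve("eq24", 0.1, 5.0, 50, omega3=2.0)
        assert (curve.samples["coordinate"] > 0.5).all()

    def test_unknown_curve_rejected(self):
        with pytest.raises(ValueError, match="unknown curve"):
            boundary_curve("eq99", 0, 1, 10)
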