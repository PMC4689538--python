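"""Linear-noise moments, stability, sensitivities, classification."""

import math

import numpy as np
import pytest

from stemlineage import (
    Controls,
    Equilibrium,
    SignPattern,
    classify_network,
    critical_symmetry,
    lna_moments,
    solve_moment_system,
    stability,
    variance_sensitivity,
)
from stemlineage.errors import InvalidParameterError, NonHyperbolicError
from stemlineage.lna import MINIMAL_PATTERNS, sensitivity_symbolic


def _random_stable_controls(rng, n=50):
    """Yield (controls, L_star, S_star) triples in the stable regime."""
    out = []
    while len(out) < n:
        c = Controls(*rng.uniform(-1.0, 1.0, size=4))
        L_star = rng.uniform(0.1, 1.0)
        S_star = rng.uniform(0.05, 1.0)
        if stability(c, L_star, S_star)[0]:
            out.append((c, L_star, S_star))
    return out


def _eq_stub(L_star=0.5, i0=100.0, j0=200.0):
    return Equilibrium(i0=i0, j0=j0, L_star=L_star, S_star=1.0, P_star=0.5,
                       kind="mixed")


class TestMoments:
    def test_model3_variances(self, model3_eq, model3_controls):
        r = lna_moments(model3_eq, model3_controls, 0.5)
        assert r.var_I == pytest.approx(115.895, abs=0.01)
        assert r.mean_I == pytest.approx(model3_eq.i0)
        assert r.mean_J == pytest.approx(model3_eq.j0)
        assert r.stable
        assert r.K_x > 0 and r.K_y > 0

    def test_model5_var_I_independent_of_symmetry(self, model5_eq, model5_controls):
        values = [
            lna_moments(model5_eq, model5_controls, s).var_I
            for s in np.arange(0.1, 1.01, 0.1)
        ]
        assert values[0] == pytest.approx(78.704, abs=0.01)
        assert all(v == pytest.approx(values[0], rel=1e-12) for v in values)

    def test_model5_var_J_at_full_symmetry(self, model5_eq, model5_controls):
        r = lna_moments(model5_eq, model5_controls, 1.0)
        assert r.var_J == pytest.approx(3055.6, abs=0.5)

    def test_requires_mixed_equilibrium(self, model5_controls):
        eq = Equilibrium(i0=1.0, j0=1.0, L_star=0.5, S_star=0.0, P_star=0.7,
                         kind="purely_asymmetric")
        with pytest.raises(InvalidParameterError):
            lna_moments(eq, model5_controls, 0.5)

    def test_degenerate_linearization_raises(self):
        c = Controls(q_x=0.0, q_y=0.0, p_x=0.0, p_y=0.0)
        with pytest.raises(NonHyperbolicError):
            lna_moments(_eq_stub(), c, 0.5)

    def test_stable_implies_positive_variances(self):
        rng = np.random.default_rng(3)
        for c, L_star, S_star in _random_stable_controls(rng, 50):
            r = lna_moments(_eq_stub(L_star), c, S_star)
            assert r.var_I > 0 and r.var_J > 0
            assert r.K_x >= 0 and r.K_y >= 0


class TestMomentSystemOracle:
    def test_matches_closed_form_on_random_stable_sets(self):
        """Brute-force solve of the moment equations reproduces the closed-form
        variances to near machine precision, including cancellation of the
        first-derivative terms of L, D and S."""
        rng = np.random.default_rng(11)
        for c, L_star, S_star in _random_stable_controls(rng, 50):
            extras = dict(zip(
                ("l_x", "l_y", "d_x", "d_y", "s_x", "s_y"),
                rng.uniform(-1.0, 1.0, size=6),
            ))
            sol = solve_moment_system(c, L_star, S_star, **extras)
            r = lna_moments(_eq_stub(L_star), c, S_star)
            assert sol["X10"] == pytest.approx(0.0, abs=1e-10)
            assert sol["X01"] == pytest.approx(0.0, abs=1e-10)
            assert sol["var_I"] == pytest.approx(r.var_I, rel=1e-10)
            assert sol["var_J"] == pytest.approx(r.var_J, rel=1e-10)

    def test_presets_agree_with_oracle(self, model3_eq, model3_controls,
                                       model5_eq, model5_controls):
        for eq, c in ((model3_eq, model3_controls), (model5_eq, model5_controls)):
            sol = solve_moment_system(c, eq.L_star, 0.5)
            r = lna_moments(eq, c, 0.5)
            assert sol["var_I"] == pytest.approx(r.var_I, rel=1e-10)
            assert sol["var_J"] == pytest.approx(r.var_J, rel=1e-10)


class TestStability:
    def test_model5_critical_symmetry_zero(self, model5_controls, model5_eq):
        stable, s_c = stability(model5_controls, model5_eq.L_star, 0.5)
        assert stable
        assert s_c == pytest.approx(0.0, abs=1e-8)

    def test_model3_critical_symmetry(self, model3_controls, model3_eq):
        # p_x < p_y here, so the stable window is S* < S_c
        stable, s_c = stability(model3_controls, model3_eq.L_star, 0.5)
        assert stable
        assert s_c == pytest.approx(1.4427, abs=2e-4)
        for s in (0.1, 0.5, 1.0):
            assert stability(model3_controls, model3_eq.L_star, s)[0]

    def test_equal_p_convention_signed_infinity(self):
        c_neg = Controls(q_x=-1.0, q_y=-0.5, p_x=0.3, p_y=0.3)
        assert critical_symmetry(c_neg, 0.5) == -math.inf
        c_pos = Controls(q_x=-1.0, q_y=0.5, p_x=0.3, p_y=0.3)
        assert critical_symmetry(c_pos, 0.5) == math.inf
        # B is then independent of S*
        assert stability(c_neg, 0.5, 0.1)[0] == stability(c_neg, 0.5, 1.0)[0]

    def test_negative_delta_always_unstable(self):
        c = Controls(q_x=-1.0, q_y=0.0, p_x=0.0, p_y=1.0)  # Delta < 0
        for s in (0.1, 0.5, 1.0):
            assert not stability(c, 0.5, s)[0]

    def test_invalid_rate_rejected(self, model5_controls):
        with pytest.raises(InvalidParameterError):
            stability(model5_controls, 0.0, 0.5)


class TestSensitivity:
    def test_closed_form_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        for c, L_star, S_star in _random_stable_controls(rng, 50):
            S_star = min(max(S_star, 0.1), 0.9)
            sens = variance_sensitivity(c, L_star, S_star)
            eq = _eq_stub(L_star)
            h = 1e-4
            fd_i = (lna_moments(eq, c, S_star + h).var_I
                    - lna_moments(eq, c, S_star - h).var_I) / (2 * h)
            fd_j = (lna_moments(eq, c, S_star + h).var_J
                    - lna_moments(eq, c, S_star - h).var_J) / (2 * h)
            assert sens.dvarI_dS == pytest.approx(fd_i, rel=1e-6, abs=1e-8)
            assert sens.dvarJ_dS == pytest.approx(fd_j, rel=1e-6, abs=1e-8)

    def test_variances_monotone_in_symmetry(self):
        """For fixed controls the variances either grow or decay with S*."""
        rng = np.random.default_rng(9)
        grid = np.linspace(0.05, 1.0, 20)
        checked = 0
        for c, L_star, _ in _random_stable_controls(rng, 80):
            if not all(stability(c, L_star, s)[0] for s in grid):
                continue
            eq = _eq_stub(L_star)
            vi = [lna_moments(eq, c, s).var_I for s in grid]
            vj = [lna_moments(eq, c, s).var_J for s in grid]
            for seq in (np.diff(vi), np.diff(vj)):
                assert np.all(seq >= -1e-12) or np.all(seq <= 1e-12)
            checked += 1
        assert checked >= 20

    def test_two_control_system_signs(self):
        # only q_x < 0 and p_y < 0: stem-cell variance flat, differentiated
        # variance shrinking with symmetry
        c1 = Controls(q_x=-0.8, q_y=0.0, p_x=0.0, p_y=-0.4)
        s1 = variance_sensitivity(c1, 0.5, 0.6)
        assert s1.dvarI_dS == 0.0
        assert s1.dvarJ_dS < 0.0
        # only p_x > 0 and q_y < 0: differentiated variance grows with symmetry
        c2 = Controls(q_x=0.0, q_y=-0.5, p_x=0.7, p_y=0.0)
        s2 = variance_sensitivity(c2, 0.5, 0.6)
        assert s2.dvarI_dS == 0.0
        assert s2.dvarJ_dS > 0.0

    def test_model5_preset_signs(self, model5_controls, model5_eq):
        sens = variance_sensitivity(model5_controls, model5_eq.L_star, 0.5)
        assert sens.dvarI_dS == pytest.approx(0.0, abs=1e-9)
        assert sens.dvarJ_dS < 0.0

    def test_symbolic_specializations_vanish(self):
        assert sensitivity_symbolic(SignPattern(*MINIMAL_PATTERNS["#1"]), "I") == 0
        assert sensitivity_symbolic(SignPattern(*MINIMAL_PATTERNS["#2"]), "I") == 0
        assert sensitivity_symbolic(SignPattern(*MINIMAL_PATTERNS["#5"]), "I") == 0
        # #3 keeps a genuinely nonzero derivative
        assert sensitivity_symbolic(SignPattern(*MINIMAL_PATTERNS["#3"]), "I") != 0


class TestClassification:
    EXPECTED = {
        "#1": ("constant", "decreasing", "symmetric"),
        "#2": ("constant", "increasing", "asymmetric"),
        "#3": ("increasing", "increasing", "asymmetric"),
        "#4": ("decreasing", "decreasing", "symmetric"),
        "#5": ("constant", "decreasing", "symmetric"),
    }

    @pytest.mark.parametrize("label", sorted(EXPECTED))
    def test_minimal_systems(self, label):
        record = classify_network(SignPattern(*MINIMAL_PATTERNS[label]))
        assert record.label == label
        trend_i, trend_j, optimal = self.EXPECTED[label]
        assert record.var_I_trend == trend_i
        assert record.var_J_trend == trend_j
        assert record.optimal_symmetry == optimal

    def test_all_zero_pattern_unstabilizable(self):
        record = classify_network(SignPattern(0, 0, 0, 0))
        assert record.label == "unstabilizable"

    def test_four_control_pattern_is_non_minimal(self):
        record = classify_network(SignPattern(1, -1, 1, 1))
        assert record.label == "non-minimal"
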