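"""Concentration-response curves, shape-parameter inversion, conversions."""

import numpy as np
import pytest

from burstfield import anesthesia as an
from burstfield.kinetics import decay_time_ratio_vec


class TestHillCurves:
    def test_excitatory_amplitude_anchors(self):
        assert an.hill_excitatory_amplitude(0.0) == 1.0
        assert an.hill_excitatory_amplitude(0.707) == pytest.approx(0.5)
        # value recovered by inverting the printed resting amplitude
        # Γ^r_ee(0.25) = 0.37703 = Γ⁰_ee (1 + f_e) H_e(0.25)
        oracle = 0.37703 / (0.18424 * 2.25)
        assert an.hill_excitatory_amplitude(0.25) == pytest.approx(oracle, rel=1e-4)

    def test_inhibitory_amplitude_anchors(self):
        assert an.hill_inhibitory_amplitude(0.0) == 1.0
        assert an.hill_inhibitory_amplitude(1e9) == pytest.approx(0.56, rel=1e-6)
        assert an.hill_inhibitory_amplitude(0.79) == pytest.approx(0.78)

    def test_decay_factor_anchors(self):
        assert an.inhibitory_decay_factor(0.0) == 1.0
        assert an.inhibitory_decay_factor(1e9) == pytest.approx(4.7, rel=1e-6)
        assert an.inhibitory_decay_factor(0.32) == pytest.approx(2.85)

    def test_monotonicity_over_clinical_range(self):
        c = np.linspace(0.0, 1.0, 400)
        assert np.all(np.diff(an.hill_excitatory_amplitude(c)) < 0)
        assert np.all(np.diff(an.hill_inhibitory_amplitude(c)) < 0)
        assert np.all(np.diff(an.inhibitory_decay_factor(c)) > 0)

    def test_negative_concentration_rejected(self):
        for fn in (an.hill_excitatory_amplitude, an.hill_inhibitory_amplitude,
                   an.inhibitory_decay_factor):
            with pytest.raises(ValueError):
                fn(-0.1)


class TestEpsilonInversion:
    def test_boundary_and_continuity(self):
        assert an.epsilon_from_kappa(1.0) == 0.0
        assert an.epsilon_from_kappa(1.0 + 1e-8) < 1e-3
        with pytest.raises(ValueError):
            an.epsilon_from_kappa(0.9)

    @pytest.mark.parametrize("kappa", [1.05, 1.2, 1.5, 2.0, 3.0, 4.5])
    def test_decay_time_fidelity_within_1_percent(self, kappa):
        eps = an.epsilon_from_kappa(kappa)
        ratio = float(decay_time_ratio_vec(eps)[0])
        assert abs(ratio - kappa) / kappa < 0.01

    def test_formula_matches_refined_value_closely(self):
        # the closed-form Lambert-W approximation is the initial guess;
        # it agrees with the exact inversion to ~1% in eps
        for kappa in (1.3, 2.0, 4.0):
            raw = an.epsilon_from_kappa(kappa, refine=False)
            ref = an.epsilon_from_kappa(kappa, refine=True)
            assert raw == pytest.approx(ref, rel=0.02)

    def test_vectorised_interpolant_consistency(self):
        ks = np.array([1.0, 1.1, 2.3, 4.6])
        vec = an.epsilon_from_kappa_vec(ks)
        for k, e in zip(ks, vec):
            assert e == pytest.approx(an.epsilon_from_kappa(float(k)), abs=1e-6)


class TestRateConstants:
    def test_eps_zero_limit(self):
        g, gt = an.rate_constants(9.1059, 0.0)
        assert g == pytest.approx(1.0 / 9.1059, rel=1e-12)
        assert gt == g

    def test_direct_substitution(self):
        g, gt = an.rate_constants(1.0, 1.0)
        assert g == pytest.approx(1.0 / (np.e - 1.0))
        assert gt == pytest.approx(np.e / (np.e - 1.0))

    def test_small_eps_branch_is_smooth(self):
        g1, _ = an.rate_constants(2.0, 9e-9)
        g2, _ = an.rate_constants(2.0, 1.1e-8)
        assert g1 == pytest.approx(g2, rel=1e-7)


class TestUnitConversions:
    def test_mac_anchors(self):
        assert an.concentration_from_mac(1.0) == pytest.approx(0.243)
        assert an.concentration_from_mac(0.5) == pytest.approx(0.1215)
        assert an.concentration_from_mac(0.0) == 0.0

    def test_percent_anchor(self):
        assert an.percent_from_mM(0.243) == pytest.approx(1.17)
        # 1.3 % ≃ 0.27 mM consistency (linear anchor, ~=0.26996)
        assert an.mM_from_percent(1.3) == pytest.approx(0.27, rel=2e-3)

    def test_round_trips(self):
        assert an.mac_from_concentration(an.concentration_from_mac(0.73)) == pytest.approx(0.73)
        assert an.mM_from_percent(an.percent_from_mM(0.4)) == pytest.approx(0.4)


class TestAnestheticState:
    def test_zero_concentration_reduces_to_base_model(self, p):
        st = an.anesthetic_state(p, 0.0)
        assert st.H_e == 1.0 and st.H_i == 1.0
        for lk in ("ee", "ei", "ie", "ii"):
            assert st.eps[lk] == 0.0
            assert st.gamma[lk] == pytest.approx(1.0 / p.cls("delta", lk))
            assert st.gamma_tilde[lk] == st.gamma[lk]
            assert st.Gamma[lk] == p.cls("Gamma", lk)

    def test_component_consistency_at_one_mac(self, p):
        c = 0.243
        st = an.anesthetic_state(p, c)
        kap = float(an.inhibitory_decay_factor(c))
        eps = an.epsilon_from_kappa(kap)
        assert st.kappa["ie"] == pytest.approx(kap)
        assert st.eps["ii"] == pytest.approx(eps)
        assert st.eps["ee"] == 0.0 and st.kappa["ei"] == 1.0
        for lk in ("ee", "ei"):
            assert st.Gamma[lk] == pytest.approx(
                p.cls("Gamma", lk) * float(an.hill_excitatory_amplitude(c)))
        for lk in ("ie", "ii"):
            assert st.Gamma[lk] == pytest.approx(
                p.cls("Gamma", lk) * float(an.hill_inhibitory_amplitude(c)))
            g, gt = an.rate_constants(p.cls("delta", lk), eps)
            assert st.gamma[lk] == pytest.approx(g, rel=1e-9)
            assert st.gamma_tilde[lk] == pytest.approx(gt, rel=1e-9)
        # γ̃ = e^ε γ throughout
        for lk in ("ee", "ei", "ie", "ii"):
            assert st.gamma_tilde[lk] == pytest.approx(
                np.exp(st.eps[lk]) * st.gamma[lk], rel=1e-12)
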