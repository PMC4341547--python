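"""Field right-hand sides, wave propagation, and stepper equivalence."""

import numpy as np
import pytest

from burstfield.anesthesia import anesthetic_state
from burstfield.equilibrium import construct_initial_state, fixed_point
from burstfield.field_dynamics import (euler_step, firing_rate, laplacian,
                                       membrane_rhs, synaptic_input_rates,
                                       wave_step)
from burstfield.params import CLASSES


class TestFiringRate:
    def test_half_maximum_at_threshold(self, p):
        assert float(firing_rate(p.mu_e, p, "e")) == pytest.approx(p.S_max_e / 2)
        assert float(firing_rate(p.mu_i, p, "i")) == pytest.approx(p.S_max_i / 2)

    def test_saturation_limits(self, p):
        assert float(firing_rate(-1e4, p, "e")) == pytest.approx(0.0, abs=1e-30)
        assert float(firing_rate(1e4, p, "e")) == pytest.approx(p.S_max_e)

    def test_strictly_increasing(self, p):
        h = np.linspace(-100.0, 0.0, 500)
        assert np.all(np.diff(firing_rate(h, p, "e")) > 0)

    def test_sigmoid_form_switch_changes_slope(self, p):
        h = p.mu_e - 3.0
        s_sqrt2 = float(firing_rate(h, p, "e"))
        s_two = float(firing_rate(h, p.copy(sigmoid_form="2"), "e"))
        assert s_two < s_sqrt2   # steeper form is smaller below threshold


class TestLaplacian:
    def test_constant_field_is_flat(self):
        assert np.all(laplacian(np.full((6, 6), 3.7), dx=1.0) == 0.0)

    def test_unit_spike_stencil_with_wrap(self):
        f = np.zeros((5, 5))
        f[0, 0] = 1.0
        lap = laplacian(f, dx=0.5)
        assert lap[0, 0] == pytest.approx(-4.0 / 0.25)
        for j, i in ((0, 1), (1, 0), (0, 4), (4, 0)):   # incl. periodic wrap
            assert lap[j, i] == pytest.approx(1.0 / 0.25)
        assert np.count_nonzero(lap) == 5

    def test_plane_wave_eigenvalue(self):
        n, dx, m = 32, 1.0, 3
        x = np.arange(n) * dx
        f = np.cos(2 * np.pi * m * x[None, :] / (n * dx)) * np.ones((n, 1))
        lam = -(2.0 - 2.0 * np.cos(2 * np.pi * m * dx / (n * dx))) / dx ** 2
        assert np.allclose(laplacian(f, dx), lam * f, atol=1e-12)


class TestMembraneRhs:
    def test_weights_at_rest_are_plus_minus_one(self, p):
        state, _, _ = construct_initial_state(p, (4, 4))
        state.h_e[...] = p.h_r_e
        for lk in CLASSES:
            state.I[lk][...] = 0.0
        state.I["ee"][...] = 1.0     # unit excitatory input only
        dh = membrane_rhs(state, p)
        assert np.allclose(dh["e"], 1.0 / p.tau_e)
        state.I["ee"][...] = 0.0
        state.I["ie"][...] = 1.0     # unit inhibitory input only
        dh = membrane_rhs(state, p)
        assert np.allclose(dh["e"], -1.0 / p.tau_e)

    def test_reversal_potential_nullifies_its_class(self, p):
        state, _, _ = construct_initial_state(p, (4, 4))
        state.h_e[...] = p.h_eq_ee
        for lk in CLASSES:
            state.I[lk][...] = 0.0
        state.I["ee"][...] = 5.0
        dh = membrane_rhs(state, p)
        # only the leak term remains
        assert np.allclose(dh["e"], (p.h_r_e - p.h_eq_ee) / p.tau_e)


class TestSynapticInputs:
    def test_equilibrium_input_rates(self, p):
        state, sp, eq = construct_initial_state(p, (4, 4))
        A = synaptic_input_rates(state, p, np.full((4, 4), p.p_ee))
        assert np.allclose(A["ee"], (p.N_beta_ee + p.N_alpha_ee) * eq.S0_e + p.p_ee)
        assert np.allclose(A["ei"], (p.N_beta_ei + p.N_alpha_ei) * eq.S0_e + p.p_ei)
        assert np.allclose(A["ie"], p.N_beta_ie * eq.S0_i)

    def test_inhibitory_inputs_ignore_flux_and_drive(self, p):
        state, _, _ = construct_initial_state(p, (4, 4))
        A1 = synaptic_input_rates(state, p, np.full((4, 4), p.p_ee))
        state.phi += 5.0
        A2 = synaptic_input_rates(state, p, np.full((4, 4), 99.0))
        assert np.allclose(A1["ie"], A2["ie"]) and np.allclose(A1["ii"], A2["ii"])
        assert not np.allclose(A1["ee"], A2["ee"])


class TestWave:
    def test_homogeneous_steady_source_converges_to_source(self):
        lam, v, dx, dt = 10.0, 2.0, 1.0, 0.05
        src = np.full((8, 8), 0.37)
        phi = np.zeros((8, 8))
        prev = phi.copy()
        for _ in range(40000):
            phi, prev = wave_step(phi, prev, src, lam, v, dx, dt), phi
        assert np.allclose(phi, 0.37, rtol=1e-6)

    def test_zero_source_uniform_decay(self):
        phi = np.full((8, 8), 1.0)
        prev = phi.copy()
        vals = []
        for _ in range(2000):
            phi, prev = wave_step(phi, prev, np.zeros((8, 8)), 10.0, 2.0, 1.0, 0.05), phi
            vals.append(phi[0, 0])
        assert np.all(np.diff(vals) < 0) and vals[-1] < 0.2

    def test_point_source_steady_decay_scale(self):
        """Steady response to a point source falls below 2 % at r = 4λ."""
        n, dx, lam, v, dt = 96, 1.0, 6.0, 2.1042, 0.05
        src = np.zeros((n, n))
        src[0, 0] = 1.0
        # oracle: steady state (1/λ² - ∇²)Φ = src/λ² solved in Fourier space
        ky = np.fft.fftfreq(n, d=dx)
        kx = np.fft.fftfreq(n, d=dx)
        eig = -(2 - 2 * np.cos(2 * np.pi * ky[:, None] * dx)) / dx ** 2 \
              - (2 - 2 * np.cos(2 * np.pi * kx[None, :] * dx)) / dx ** 2
        phi_hat = np.fft.fft2(src / lam ** 2) / (1.0 / lam ** 2 - eig)
        oracle = np.fft.ifft2(phi_hat).real
        assert oracle[0, 4 * int(lam)] / oracle[0, 0] < 0.02
        # the time stepper converges to the same steady state
        phi = np.zeros((n, n))
        prev = phi.copy()
        for _ in range(30000):
            phi, prev = wave_step(phi, prev, src, lam, v, dx, dt), phi
        assert np.allclose(phi, oracle, atol=2e-5 * oracle[0, 0])


class TestStepperProperties:
    def _mini_setup(self, p, shape=(8, 8)):
        state, sp, eq = construct_initial_state(p, shape)
        anes = anesthetic_state(p, 0.0)
        return state, sp, anes

    def test_translation_equivariance_on_torus(self, p, rng):
        state, sp, anes = self._mini_setup(p)
        state.h_e += 0.5 * rng.standard_normal(state.h_e.shape)
        noise = p.p_ee * (1.0 + 0.05 * rng.standard_normal(state.h_e.shape))
        shift = (3, 5)

        def roll_state(s):
            out = s.copy()
            out.h_e = np.roll(s.h_e, shift, (0, 1))
            out.h_i = np.roll(s.h_i, shift, (0, 1))
            out.C_e = np.roll(s.C_e, shift, (0, 1))
            out.C_i = np.roll(s.C_i, shift, (0, 1))
            out.phi = np.roll(s.phi, shift, (1, 2))
            out.phi_prev = np.roll(s.phi_prev, shift, (1, 2))
            for lk in CLASSES:
                out.I[lk] = np.roll(s.I[lk], shift, (0, 1))
                out.J[lk] = np.roll(s.J[lk], shift, (0, 1))
            return out

        a = euler_step(state, p, anes, sp, noise, 1.0, 0.05)
        b = euler_step(roll_state(state), p, anes, sp,
                       np.roll(noise, shift, (0, 1)), 1.0, 0.05)
        assert roll_state(a).max_abs_diff(b) < 1e-14

    def test_freeze_C_keeps_efficacies_constant(self, p):
        state, sp, anes = self._mini_setup(p)
        state.h_e += 2.0   # well off equilibrium: depletion would act
        s = state
        for _ in range(200):
            s = euler_step(s, p, anes, sp, np.full((8, 8), p.p_ee), 1.0, 0.05,
                           freeze_C=True)
        assert np.all(s.C_e == 1.0) and np.all(s.C_i == 1.0)

    def test_frozen_trajectories_independent_of_depletion_factors(self, p):
        """With C ≡ 1 the extended (non-bursting) model is recovered:
        the f_l parameters must not influence the trajectory at all."""
        from burstfield.slow_synapse import SlowSynapseParams

        state, sp, anes = self._mini_setup(p)
        state.h_e += 1.0
        sp_alt = SlowSynapseParams.from_model(p.copy(f_e=0.3, f_i=1.9),
                                              sp.S0_e, sp.S0_i)
        a, b = state, state.copy()
        for _ in range(200):
            drive = np.full((8, 8), p.p_ee)
            a = euler_step(a, p, anes, sp, drive, 1.0, 0.05, freeze_C=True)
            b = euler_step(b, p, anes, sp_alt, drive, 1.0, 0.05, freeze_C=True)
        assert a.max_abs_diff(b) == 0.0


def test_compiled_kernel_matches_reference_backend(p):
    """The fused numba stepper reproduces the numpy reference trajectory."""
    from burstfield import integrator as I

    grid = I.Grid(16, 16)
    prot = I.constant_protocol(0.25, 0.2)
    a = I.run(p, grid, prot, seed=3, backend="numba")
    b = I.run(p, grid, prot, seed=3, backend="reference")
    fa, fb = a.final_state, b.final_state
    assert fa.max_abs_diff(fb) < 1e-9
    assert np.array_equal(a.fields["h_e"], b.fields["h_e"])
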