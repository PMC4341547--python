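"""Right-hand sides of the bursting neural field model on a toroidal grid.

This module is the plain-numpy reference implementation of the coupled
dynamics: conductance-weighted membrane equations for the mean soma
potentials h_e, h_i; bi-exponential PSP kinetics integrated as a cascade of
two first-order equations per synaptic class; damped-wave cortico-cortical
propagation of the depletion-scaled excitatory firing rate; and the slow
synaptic efficacy fields C_e, C_i.  The production stepper in
``burstfield._kernel`` is a fused compiled version of exactly these
operations and is regression-tested against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .anesthesia import AnestheticState
from .params import CLASSES, E_CLASSES, ModelParams
from .slow_synapse import SlowSynapseParams, synaptic_rhs

__all__ = ["FieldState", "firing_rate", "synaptic_input_rates",
           "membrane_rhs", "psp_rhs", "wave_step", "laplacian", "euler_step"]


@dataclass
class FieldState:
    """All dynamical fields on the (ny, nx) grid.

    ``I``/``J`` hold the PSP level and its cascade auxiliary per synaptic
    class; ``phi``/``phi_prev`` are the current and previous time levels of
    the cortico-cortical flux (the wave update is a three-level scheme).
    When the two excitatory-source classes share identical propagation
    parameters they share a single flux field (``phi_index`` maps class →
    field).
    """

    h_e: np.ndarray
    h_i: np.ndarray
    I: Dict[str, np.ndarray]
    J: Dict[str, np.ndarray]
    phi: np.ndarray              # (nphi, ny, nx)
    phi_prev: np.ndarray
    C_e: np.ndarray
    C_i: np.ndarray
    phi_index: Dict[str, int] = field(default_factory=lambda: {"ee": 0, "ei": 0})

    def copy(self) -> "FieldState":
        return FieldState(
            h_e=self.h_e.copy(), h_i=self.h_i.copy(),
            I={k: v.copy() for k, v in self.I.items()},
            J={k: v.copy() for k, v in self.J.items()},
            phi=self.phi.copy(), phi_prev=self.phi_prev.copy(),
            C_e=self.C_e.copy(), C_i=self.C_i.copy(),
            phi_index=dict(self.phi_index))

    def max_abs_diff(self, other: "FieldState") -> float:
        out = max(np.max(np.abs(self.h_e - other.h_e)),
                  np.max(np.abs(self.h_i - other.h_i)),
                  np.max(np.abs(self.C_e - other.C_e)),
                  np.max(np.abs(self.C_i - other.C_i)),
                  np.max(np.abs(self.phi - other.phi)))
        for lk in CLASSES:
            out = max(out, np.max(np.abs(self.I[lk] - other.I[lk])),
                      np.max(np.abs(self.J[lk] - other.J[lk])))
        return float(out)


def firing_rate(h, p: ModelParams, population: str):
    """Sigmoidal mean firing rate S_k(h) in 1/ms.

    S = S_max / (1 + exp(-q (h - mu)/sigma)) with q = sqrt(2) by default
    (see ModelParams.sigmoid_form).
    """
    if population not in ("e", "i"):
        raise ValueError("population must be 'e' or 'i'")
    mu = getattr(p, f"mu_{population}")
    sigma = getattr(p, f"sigma_{population}")
    smax = getattr(p, f"S_max_{population}")
    q = p.sigmoid_slope()
    h = np.asarray(h, dtype=float)
    return smax / (1.0 + np.exp(-q * (h - mu) / sigma))


def laplacian(f: np.ndarray, dx: float) -> np.ndarray:
    """Five-point-stencil Laplacian with periodic (toroidal) wrap."""
    return (np.roll(f, 1, axis=0) + np.roll(f, -1, axis=0)
            + np.roll(f, 1, axis=1) + np.roll(f, -1, axis=1) - 4.0 * f) / dx ** 2


def synaptic_input_rates(state: FieldState, p: ModelParams,
                         p_ee_field) -> Dict[str, np.ndarray]:
    """Axonal pulse rates A_lk (1/ms) driving each PSP class.

    Excitatory-source classes receive local (depletion-scaled), cortico-
    cortical and extracortical input; inhibitory-source classes are local
    only.  The cortico-cortical flux already carries the source's C_e
    through the wave equation's source term.
    """
    S_e = firing_rate(state.h_e, p, "e")
    S_i = firing_rate(state.h_i, p, "i")
    local_e = state.C_e * S_e
    local_i = state.C_i * S_i
    return {
        "ee": p.N_beta_ee * local_e + p.N_alpha_ee * state.phi[state.phi_index["ee"]] + p_ee_field,
        "ei": p.N_beta_ei * local_e + p.N_alpha_ei * state.phi[state.phi_index["ei"]] + p.p_ei,
        "ie": p.N_beta_ie * local_i,
        "ii": p.N_beta_ii * local_i,
    }


def membrane_rhs(state: FieldState, p: ModelParams) -> Dict[str, np.ndarray]:
    """dh_k/dt (mV/ms) with conductance-like reversal weighting.

    The synaptic weight ψ_lk(h) = (h_eq_lk - h)/|h_eq_lk - h_r_k| is +1 for
    excitatory and -1 for inhibitory input at the resting potential and
    vanishes at the respective reversal potential.
    """
    out = {}
    for k in ("e", "i"):
        h = getattr(state, f"h_{k}")
        acc = getattr(p, f"h_r_{k}") - h
        for l in ("e", "i"):
            lk = l + k
            h_eq = p.cls("h_eq", lk)
            denom = abs(h_eq - getattr(p, f"h_r_{k}"))
            acc = acc + (h_eq - h) / denom * state.I[lk]
        out[k] = acc / getattr(p, f"tau_{k}")
    return out


def psp_rhs(state: FieldState, p: ModelParams, anes: AnestheticState,
            A: Dict[str, np.ndarray]):
    """Cascade form of the bi-exponential PSP filter.

    dI/dt = γ̃ (J - I),  dJ/dt = γ (g A - J)  with steady gain
    g = e^{γδ} Γ_lk(c) / γ.  Depletion enters through A, not the gain.
    Returns (dI, dJ) dicts in mV/ms.
    """
    dI, dJ = {}, {}
    for lk in CLASSES:
        g = anes.gamma[lk]
        gt = anes.gamma_tilde[lk]
        gain = anes.gain(p, lk)
        dI[lk] = gt * (state.J[lk] - state.I[lk])
        dJ[lk] = g * (gain * A[lk] - state.J[lk])
    return dI, dJ


def wave_step(phi_now: np.ndarray, phi_prev: np.ndarray, source: np.ndarray,
              lam: float, v: float, dx: float, dt: float) -> np.ndarray:
    """Advance the damped-wave flux equation by one step; returns Φ(t+Δt).

    The expanded form (1/v²)Φ_tt + (2/(vλ))Φ_t + Φ/λ² - ∇²Φ = source/λ² is
    discretised with a centred three-level scheme in time (current,
    previous and future values; solved for the future one) and the
    periodic five-point Laplacian in space.
    """
    a = 1.0 / (v * dt) ** 2
    b = 1.0 / (v * lam * dt)       # from the centred first derivative
    rhs = (source / lam ** 2 + laplacian(phi_now, dx) - phi_now / lam ** 2
           + 2.0 * a * phi_now - a * phi_prev + b * phi_prev)
    return rhs / (a + b)


def euler_step(state: FieldState, p: ModelParams, anes: AnestheticState,
               sp: SlowSynapseParams, p_ee_field, dx: float, dt: float,
               freeze_C: bool = False) -> FieldState:
    """One forward-Euler step of the full system (reference implementation).

    All subsystems advance with the same Δt from the same time level; the
    flux uses the three-level wave scheme.  With ``freeze_C`` the slow
    efficacies stay at their current values (C ≡ const recovers the
    extended, non-bursting model when C = 1).
    """
    A = synaptic_input_rates(state, p, p_ee_field)
    dh = membrane_rhs(state, p)
    dI, dJ = psp_rhs(state, p, anes, A)
    S_e = firing_rate(state.h_e, p, "e")
    S_i = firing_rate(state.h_i, p, "i")
    source = state.C_e * S_e

    new = state.copy()
    new.h_e = state.h_e + dt * dh["e"]
    new.h_i = state.h_i + dt * dh["i"]
    for lk in CLASSES:
        new.I[lk] = state.I[lk] + dt * dI[lk]
        new.J[lk] = state.J[lk] + dt * dJ[lk]
    nphi = state.phi.shape[0]
    for j in range(nphi):
        lk = [c for c in E_CLASSES if state.phi_index[c] == j][0]
        new.phi[j] = wave_step(state.phi[j], state.phi_prev[j], source,
                               p.cls("lambda", lk), p.cls("v", lk), dx, dt)
    new.phi_prev = state.phi.copy()
    if not freeze_C:
        new.C_e = state.C_e + dt * synaptic_rhs(state.C_e, S_e, sp, "e")
        new.C_i = state.C_i + dt * synaptic_rhs(state.C_i, S_i, sp, "i")
    if not (np.all(np.isfinite(new.h_e)) and np.all(np.isfinite(new.h_i))):
        raise FloatingPointError("field state diverged (non-finite h)")
    return new


def make_homogeneous_state(shape, h_e: float, h_i: float, I: Dict[str, float],
                           phi_value: float, nphi: int,
                           phi_index: Optional[Dict[str, int]] = None) -> FieldState:
    """Spatially constant FieldState with consistent cascade and wave history."""
    ny, nx = shape
    full = lambda v: np.full((ny, nx), float(v))
    return FieldState(
        h_e=full(h_e), h_i=full(h_i),
        I={lk: full(I[lk]) for lk in CLASSES},
        J={lk: full(I[lk]) for lk in CLASSES},   # steady cascade: J = I
        phi=np.stack([full(phi_value)] * nphi),
        phi_prev=np.stack([full(phi_value)] * nphi),
        C_e=full(1.0), C_i=full(1.0),
        phi_index=phi_index or {"ee": 0, "ei": 0 if nphi == 1 else 1},
    )
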