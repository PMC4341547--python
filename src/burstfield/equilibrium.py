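"""Spatially homogeneous fixed point and construction of the initial state.

With the extracortical drive held at its mean, the fast subsystem (membrane
potentials, PSP levels, cortico-cortical flux) admits a static homogeneous
solution.  Because every PSP level is slaved to the firing rates at steady
state, the ten-component root reduces to two unknowns (h_e, h_i):

    Φ*_ek = S_e(h_e)                       (steady wave, C_e = 1)
    I*_ek = g_ek [(N^β_ek + N^α_ek) S_e(h_e) + p_ek]
    I*_ik = g_ik  N^β_ik S_i(h_i)
    0 = h^r_k - h_k + Σ_l ψ_lk(h_k) I*_lk

with steady gains g_lk = e^{γδ}Γ_lk(c)/γ.  The root continued from the
resting potentials is returned; a coarse scan reports (but does not
resolve) any additional sign changes.

The combined initial state freezes the slow system's reference firing
rates at the c = 0 root (S⁰_l = S_l(h*_l)) and sets C_l = 1, which makes
the constructed state exactly stationary under noise-free integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .anesthesia import AnestheticState, anesthetic_state
from .field_dynamics import FieldState, firing_rate, make_homogeneous_state
from .params import CLASSES, E_CLASSES, ModelParams
from .slow_synapse import SlowSynapseParams

__all__ = ["EquilibriumResult", "fixed_point", "construct_initial_state"]

_H_SCAN = (-90.0, -40.0)   # mV window for the multiplicity scan


@dataclass
class EquilibriumResult:
    h_e: float
    h_i: float
    S0_e: float               # 1/ms
    S0_i: float
    I: Dict[str, float]       # mV
    phi: float                # 1/ms (shared steady flux C_e·S_e)
    residual_norm: float      # max normalised residual of the full system
    anes: AnestheticState
    other_roots: List[Tuple[float, float]] = field(default_factory=list)


def _steady_I(p: ModelParams, anes: AnestheticState, S_e: float, S_i: float
              ) -> Dict[str, float]:
    out = {}
    for lk in CLASSES:
        gain = anes.gain(p, lk)
        if lk in E_CLASSES:
            out[lk] = gain * ((p.cls("N_beta", lk) + p.cls("N_alpha", lk)) * S_e
                              + p.cls("p", lk))
        else:
            out[lk] = gain * p.cls("N_beta", lk) * S_i
    return out


def _membrane_residuals(p: ModelParams, h_e: float, h_i: float,
                        I: Dict[str, float]) -> Tuple[float, float]:
    res = []
    for k, h in (("e", h_e), ("i", h_i)):
        acc = getattr(p, f"h_r_{k}") - h
        for l in ("e", "i"):
            lk = l + k
            h_eq = p.cls("h_eq", lk)
            acc += (h_eq - h) / abs(h_eq - getattr(p, f"h_r_{k}")) * I[lk]
        res.append(acc)
    return res[0], res[1]


def fixed_point(p: ModelParams, c: float = 0.0,
                scan_points: int = 51) -> EquilibriumResult:
    """Solve for the homogeneous fixed point of the fast system at c (mM).

    Robust nested bracketing: for each h_e the inhibitory membrane equation
    is monotone in h_i and solved by brentq; the remaining scalar equation
    in h_e is then bracketed on a coarse scan and solved from the bracket
    containing the continuation of the resting state.  Raises RuntimeError
    with diagnostics if no bracket is found.
    """
    anes = anesthetic_state(p, c)

    def F(h_e: float, h_i: float) -> Tuple[float, float]:
        S_e = float(firing_rate(h_e, p, "e"))
        S_i = float(firing_rate(h_i, p, "i"))
        I = _steady_I(p, anes, S_e, S_i)
        return _membrane_residuals(p, h_e, h_i, I)

    def h_i_of(h_e: float) -> float:
        return brentq(lambda hi: F(h_e, hi)[1], -120.0, 60.0, xtol=1e-13)

    def Fe_red(h_e: float) -> float:
        return F(h_e, h_i_of(h_e))[0]

    hs = np.linspace(*_H_SCAN, scan_points)
    vals = np.array([Fe_red(h) for h in hs])
    sgn = np.sign(vals)
    brackets = [(hs[i], hs[i + 1]) for i in range(len(hs) - 1)
                if sgn[i] != sgn[i + 1]]
    if not brackets:
        raise RuntimeError(
            f"no fixed point bracketed for c={c} mM on {_H_SCAN}; "
            f"reduced residual range [{vals.min():.3g}, {vals.max():.3g}]")

    roots = [(brentq(Fe_red, a, b, xtol=1e-13),) for a, b in brackets]
    roots = [(he, h_i_of(he)) for (he,) in roots]
    # continuation from rest: the root reached by following the residual
    # uphill from h_r_e (Fe_red(h_r_e) > 0 for all admissible sets; the
    # first crossing above h_r_e is the continued root)
    main = min(roots, key=lambda r: abs(r[0] - p.h_r_e) if r[0] >= p.h_r_e
               else np.inf)
    h_e, h_i = main

    S0_e = float(firing_rate(h_e, p, "e"))
    S0_i = float(firing_rate(h_i, p, "i"))
    I = _steady_I(p, anes, S0_e, S0_i)
    fe, fi = _membrane_residuals(p, h_e, h_i, I)

    # normalised residual of the full system: membrane equations in mV
    # relative to the threshold spread; PSP/flux/slow equations vanish
    # identically at the constructed values, included for completeness
    res = [abs(fe) / p.sigma_e, abs(fi) / p.sigma_i]
    for lk in CLASSES:
        gain_A = I[lk]  # by construction J = I = g·A
        res.append(abs(I[lk] - gain_A) / max(abs(I[lk]), 1.0))
    res.append(0.0)  # Φ - C_e S_e with Φ := S0_e, C_e = 1
    res.extend([0.0, 0.0])  # slow system at S = S⁰, C = 1

    return EquilibriumResult(
        h_e=h_e, h_i=h_i, S0_e=S0_e, S0_i=S0_i, I=I, phi=S0_e,
        residual_norm=float(max(res)), anes=anes,
        other_roots=[r for r in roots if r != main])


def construct_initial_state(p: ModelParams, shape: Tuple[int, int],
                            f_e: Optional[np.ndarray] = None,
                            f_i: Optional[np.ndarray] = None,
                            ) -> Tuple[FieldState, SlowSynapseParams, EquilibriumResult]:
    """Homogeneous stationary initial state from the c = 0 fixed point.

    Returns the field state (C_e = C_i = 1, wave history static), the
    frozen slow-system constants (S⁰_l recorded from the root, optional
    per-point f maps honoured), and the equilibrium result itself.
    """
    eq = fixed_point(p, 0.0)
    lam_shared = (p.lambda_ee == p.lambda_ei) and (p.v_ee == p.v_ei)
    nphi = 1 if lam_shared else 2
    phi_index = {"ee": 0, "ei": 0} if lam_shared else {"ee": 0, "ei": 1}
    state = make_homogeneous_state(shape, eq.h_e, eq.h_i, eq.I,
                                   phi_value=eq.phi, nphi=nphi,
                                   phi_index=phi_index)
    sp = SlowSynapseParams.from_model(p, eq.S0_e, eq.S0_i, f_e=f_e, f_i=f_i)
    return state, sp, eq
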