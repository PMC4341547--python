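"""Isoflurane concentration-response parameterization.

Maps an aqueous isoflurane concentration c (mM) onto every
concentration-dependent quantity of the model:

* Hill-type amplitude factors H_e(c), H_i(c) scaling the PSP peak
  amplitudes Γ_lk(c) = Γ⁰_lk H_l(c);
* the inhibitory decay-time prolongation κ_ik(c) (excitatory decay times
  are unaffected, κ_ek ≡ 1);
* the PSP shape parameter ε_lk obtained by inverting the decay-time
  prolongation, via a Lambert-W closed-form approximation refined
  numerically against the exact bi-exponential decay time;
* the resulting rate constants γ_lk(c), γ̃_lk(c) (rise times δ_lk are
  concentration-independent by construction).

Clinical unit conversions are linear anchors: 1 MAC ≃ 1.17 % inspired
≃ 0.243 mM aqueous at normal body temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.special import lambertw

from .kinetics import decay_time_ratio_vec, rate_constants_from_eps
from .params import CLASSES, ModelParams

__all__ = [
    "MM_PER_MAC", "PERCENT_PER_MAC", "KAPPA_MAX",
    "hill_excitatory_amplitude", "hill_inhibitory_amplitude",
    "inhibitory_decay_factor", "epsilon_from_kappa", "rate_constants",
    "concentration_from_mac", "mac_from_concentration", "percent_from_mM",
    "mM_from_percent", "AnestheticState", "anesthetic_state",
]

MM_PER_MAC = 0.243         # mM aqueous per 1 MAC isoflurane
PERCENT_PER_MAC = 1.17     # % inspired per 1 MAC
KAPPA_MAX = 4.7            # asymptote of the decay-prolongation Hill curve

# Hill-curve constants (concentrations in mM)
_HE_C50, _HE_N = 0.707, 2.22
_HI_C50, _HI_N, _HI_FLOOR = 0.79, 2.6, 0.56
_K_C50, _K_N, _K_CEIL = 0.32, 2.7, 4.7


def _check_c(c):
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    return c


def hill_excitatory_amplitude(c):
    """H_e(c): fractional excitatory PSP amplitude; 1 at c=0, → 0."""
    c = _check_c(c)
    a = _HE_C50 ** _HE_N
    return a / (a + c ** _HE_N)


def hill_inhibitory_amplitude(c):
    """H_i(c): fractional inhibitory PSP amplitude; 1 at c=0, → 0.56."""
    c = _check_c(c)
    a = _HI_C50 ** _HI_N
    return (a + _HI_FLOOR * c ** _HI_N) / (a + c ** _HI_N)


def inhibitory_decay_factor(c):
    """κ_ik(c): inhibitory decay-time prolongation; 1 at c=0, → 4.7."""
    c = _check_c(c)
    a = _K_C50 ** _K_N
    return (a + _K_CEIL * c ** _K_N) / (a + c ** _K_N)


# ----------------------------------------------------------------------
# shape parameter from decay prolongation

def _epsilon_formula(kappa):
    """Closed-form Lambert-W approximation of ε(κ) (W₋₁ branch).

    Continuous at κ = 1 with ε(1) = 0: the W argument equals -1/e there,
    where W₋₁ = -1 cancels the 1/κ² term exactly.
    """
    kappa = np.asarray(kappa, dtype=float)
    km1 = np.maximum(kappa - 1.0, 0.0)
    arg = np.exp(-0.23630 / kappa ** 2) / (1.0 - 3.1462 * kappa)
    # the printed constants put the κ = 1 limit a few 1e-7 outside the
    # W₋₁ domain [-1/e, 0); clamp that rounding, reject genuine excursions
    inv_e = np.exp(-1.0)
    if np.any(arg < -inv_e - 1e-5):
        raise ValueError("Lambert-W argument left the W₋₁ branch domain")
    arg = np.clip(arg, -inv_e, -1e-300)
    # scipy's W₋₁ does not converge at the branch point -1/e where W = -1
    at_branch = arg <= -inv_e + 1e-14
    w = np.where(at_branch, -1.0,
                 lambertw(np.where(at_branch, -0.1, arg), -1).real)
    out = (np.exp(2.5466 - 1.3394 * kappa) * np.sqrt(km1)
           + (np.exp(-1.2699 * km1) - 1.0) * (1.0 / kappa ** 2 + w))
    return np.maximum(out, 0.0)


def epsilon_from_kappa(kappa: float, refine: bool = True) -> float:
    """Shape parameter ε achieving decay-time prolongation κ at fixed δ.

    The Lambert-W approximation formula provides the value (and the
    initial bracket); with ``refine=True`` (default) the result is
    polished by a bracketed root solve on the exact closed-form
    bi-exponential decay-time ratio, so that ζ(ε)/ζ(0) = κ to ~1e-10.
    """
    if kappa < 1.0:
        raise ValueError("kappa must be >= 1")
    if kappa - 1.0 < 1e-12:
        return 0.0
    e0 = float(_epsilon_formula(kappa))
    if not refine:
        return e0

    def f(e):
        return float(decay_time_ratio_vec(e)[0]) - kappa

    # bracket from ε = 0, where the ratio is exactly 1 < κ (the closed
    # alpha form): robust against cancellation noise at tiny ε
    hi = 1.1 * e0 + 1e-6
    for _ in range(200):
        if f(hi) > 0:
            break
        hi *= 1.5
    else:  # pragma: no cover
        raise RuntimeError("failed to bracket epsilon(kappa)")
    return brentq(f, 0.0, hi, xtol=1e-12)


@lru_cache(maxsize=1)
def _eps_of_kappa_interp() -> PchipInterpolator:
    """Dense monotone interpolant of the refined ε(κ) over (1, κ_max].

    ε behaves like sqrt(κ-1) near κ = 1, so the grid is quadratic in the
    sqrt variable to keep the interpolation error uniform (~1e-9).
    """
    s = np.linspace(0.0, np.sqrt(KAPPA_MAX - 1.0), 160)
    kappas = 1.0 + s ** 2
    eps0 = _epsilon_formula(kappas)
    eps = eps0.copy()
    # vectorised Newton refinement on the exact decay-time ratio
    for _ in range(60):
        r = decay_time_ratio_vec(eps)
        de = np.full_like(eps, 1e-6)
        r2 = decay_time_ratio_vec(eps + de)
        slope = (r2 - r) / de
        step = np.where(slope > 1e-12, (kappas - r) / np.maximum(slope, 1e-12), 0.0)
        step = np.clip(step, -0.5, 0.5)
        eps = np.maximum(eps + step, 0.0)
        if np.max(np.abs(step)) < 1e-11:
            break
    eps[0] = 0.0
    return PchipInterpolator(kappas, eps, extrapolate=False)


def epsilon_from_kappa_vec(kappa) -> np.ndarray:
    """Vectorised refined ε(κ) through the cached interpolant."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 1.0) or np.any(kappa > KAPPA_MAX):
        raise ValueError(f"kappa must lie in [1, {KAPPA_MAX}]")
    return np.asarray(_eps_of_kappa_interp()(kappa))


def rate_constants(delta: float, eps: float) -> Tuple[float, float]:
    """(γ, γ̃) in 1/ms for rise time δ (ms) and shape ε (see kinetics)."""
    return rate_constants_from_eps(delta, eps)


# ----------------------------------------------------------------------
# clinical unit conversions

def concentration_from_mac(mac):
    """MAC → aqueous mM (1 MAC = 0.243 mM)."""
    mac = np.asarray(mac, dtype=float)
    if np.any(mac < 0):
        raise ValueError("MAC must be non-negative")
    out = mac * MM_PER_MAC
    return float(out) if out.ndim == 0 else out


def mac_from_concentration(c):
    """Aqueous mM → MAC."""
    return _check_c(c) / MM_PER_MAC


def percent_from_mM(c):
    """Aqueous mM → % inspired gas (via the MAC anchor)."""
    return _check_c(c) / MM_PER_MAC * PERCENT_PER_MAC


def mM_from_percent(pct):
    """% inspired gas → aqueous mM."""
    pct = np.asarray(pct, dtype=float)
    if np.any(pct < 0):
        raise ValueError("percent must be non-negative")
    return pct / PERCENT_PER_MAC * MM_PER_MAC


# ----------------------------------------------------------------------
# assembled state

@dataclass
class AnestheticState:
    """All concentration-derived scalars at one concentration c (mM).

    Per-class dictionaries are keyed by the class labels in
    :data:`burstfield.params.CLASSES`.
    """

    c: float
    H_e: float
    H_i: float
    kappa: Dict[str, float]         # κ_lk (κ_ek ≡ 1)
    eps: Dict[str, float]           # ε_lk (ε_ek ≡ 0)
    gamma: Dict[str, float]         # γ_lk(c), 1/ms
    gamma_tilde: Dict[str, float]   # γ̃_lk(c), 1/ms
    Gamma: Dict[str, float]         # Γ_lk(c) = Γ⁰_lk H_l(c), mV

    def gain(self, p: ModelParams, lk: str) -> float:
        """Steady PSP gain e^{γδ}·Γ(c)/γ (mV·ms) for class lk."""
        g = self.gamma[lk]
        return float(np.exp(g * p.cls("delta", lk)) * self.Gamma[lk] / g)


def anesthetic_state(p: ModelParams, c: float) -> AnestheticState:
    """Assemble the full concentration-dependent state at c (mM)."""
    c = float(c)
    if c < 0:
        raise ValueError("concentration must be non-negative")
    H_e = float(hill_excitatory_amplitude(c))
    H_i = float(hill_inhibitory_amplitude(c))
    kap_i = float(inhibitory_decay_factor(c))
    eps_i = epsilon_from_kappa(kap_i)

    kappa, eps, gamma, gamma_tilde, Gamma = {}, {}, {}, {}, {}
    for lk in CLASSES:
        src = lk[0]
        kappa[lk] = kap_i if src == "i" else 1.0
        eps[lk] = eps_i if src == "i" else 0.0
        g, gt = rate_constants(p.cls("delta", lk), eps[lk])
        gamma[lk], gamma_tilde[lk] = g, gt
        Gamma[lk] = p.cls("Gamma", lk) * (H_i if src == "i" else H_e)
    return AnestheticState(c=c, H_e=H_e, H_i=H_i, kappa=kappa, eps=eps,
                           gamma=gamma, gamma_tilde=gamma_tilde, Gamma=Gamma)
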