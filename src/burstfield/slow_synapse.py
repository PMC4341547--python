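"""Slow synaptic resource depletion and recovery.

The peak PSP amplitudes are demoted from parameters to slow state
variables: high pre-synaptic firing depletes them (vesicle depletion,
receptor desensitization) and they recover toward a resting value Γ^r_lk
with time constant τ^rec_l.  In the scaled form used throughout,
Γ_lk(x,t) = Γ⁰_lk C_l(x,t) with two efficacy fields C_e, C_i obeying

    τ^rec_l ∂C_l/∂t = 1 + f_l - (1 + f_l S_l/S⁰_l) C_l .

C_l = 1 at the constructed equilibrium (firing at S⁰_l) and C_l → 1 + f_l
with no activity, i.e. Γ → Γ^r_lk = Γ⁰_lk (1 + f_l).  Under anesthesia the
effective amplitude is additionally scaled by the Hill factor:
Γ_lk(x,t,c) = Γ⁰_lk C_l(x,t) H_l(c).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Union

import numpy as np

from .anesthesia import hill_excitatory_amplitude, hill_inhibitory_amplitude
from .params import CLASSES, ModelParams

__all__ = ["SlowSynapseParams", "synaptic_rhs", "resting_amplitudes",
           "effective_amplitude"]

ArrayOrFloat = Union[float, np.ndarray]


@dataclass
class SlowSynapseParams:
    """Frozen slow-system constants for one run.

    The reference firing rates S⁰_l are those of the c = 0 constructed
    equilibrium and are *not* recomputed as the concentration changes;
    this is what makes the combined initial state exactly stationary.
    ``f_e``/``f_i`` may be scalars or per-grid-point maps.
    """

    tau_rec_e: float
    tau_rec_i: float
    f_e: ArrayOrFloat
    f_i: ArrayOrFloat
    S0_e: float
    S0_i: float

    def __post_init__(self):
        for l in ("e", "i"):
            if not getattr(self, f"S0_{l}") > 0:
                raise ValueError(
                    f"S0_{l} must be positive: the constructed equilibrium "
                    "requires non-zero population firing")
            if np.any(np.asarray(getattr(self, f"f_{l}")) <= 0):
                raise ValueError(f"f_{l} must be strictly positive")

    def f(self, l: str) -> ArrayOrFloat:
        return getattr(self, f"f_{l}")

    def rho_dep(self, l: str) -> ArrayOrFloat:
        """Depletion coupling ρ^dep_l = f_l / (τ^rec_l S⁰_l) (per spike)."""
        return self.f(l) / (getattr(self, f"tau_rec_{l}") * getattr(self, f"S0_{l}"))

    @classmethod
    def from_model(cls, p: ModelParams, S0_e: float, S0_i: float,
                   f_e: Optional[ArrayOrFloat] = None,
                   f_i: Optional[ArrayOrFloat] = None) -> "SlowSynapseParams":
        return cls(tau_rec_e=p.tau_rec_e, tau_rec_i=p.tau_rec_i,
                   f_e=p.f_e if f_e is None else f_e,
                   f_i=p.f_i if f_i is None else f_i,
                   S0_e=S0_e, S0_i=S0_i)


def synaptic_rhs(C: ArrayOrFloat, S: ArrayOrFloat, sp: SlowSynapseParams,
                 population: str) -> ArrayOrFloat:
    """dC_l/dt (1/ms) for efficacy C under instantaneous firing rate S (1/ms)."""
    if population not in ("e", "i"):
        raise ValueError("population must be 'e' or 'i'")
    f = sp.f(population)
    S0 = getattr(sp, f"S0_{population}")
    tau = getattr(sp, f"tau_rec_{population}")
    return (1.0 + f - (1.0 + (S / S0) * f) * C) / tau


def resting_amplitudes(p: ModelParams, c: float,
                       f_override: Optional[Dict[str, ArrayOrFloat]] = None,
                       ) -> Dict[str, ArrayOrFloat]:
    """Resting (no-activity) amplitudes Γ^r_lk(c) = Γ⁰_lk (1+f_l) H_l(c), mV.

    ``f_override`` may supply per-population replacements for f_e/f_i,
    scalar or per-grid-point (e.g. a heterogeneity patch).
    """
    f_override = f_override or {}
    H = {"e": hill_excitatory_amplitude(c), "i": hill_inhibitory_amplitude(c)}
    out = {}
    for lk in CLASSES:
        src = lk[0]
        f = f_override.get(src, getattr(p, f"f_{src}"))
        out[lk] = p.cls("Gamma", lk) * (1.0 + f) * H[src]
    return out


def effective_amplitude(Gamma0: float, C: ArrayOrFloat, H: float) -> ArrayOrFloat:
    """Instantaneous effective amplitude Γ⁰·C·H (mV)."""
    if np.any(np.asarray(C) < 0):
        raise ValueError("efficacy C must be non-negative")
    return Gamma0 * C * H
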