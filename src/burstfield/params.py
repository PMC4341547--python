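"""Model parameter set for the bursting neural field model.

All quantities are held in a consistent internal unit system:
milliseconds, millimetres, millivolts and millimolar, with rates in 1/ms.
This matches the printed parameter table of the underlying EEG model, so no
unit conversion is ever applied to a stored value.

Synaptic classes are doubly indexed, pre-synaptic source first and
post-synaptic target second, in the fixed order ``("ee", "ei", "ie", "ii")``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields, replace
from typing import List

import yaml

#: Fixed ordering of the four synaptic classes (source, target).
CLASSES = ("ee", "ei", "ie", "ii")

#: The two excitatory-source classes that receive cortico-cortical input.
E_CLASSES = ("ee", "ei")


@dataclass
class ModelParams:
    """Mean population parameters of the bursting neural field model.

    Defaults are the published "bi-phasic" parameter set that produces
    burst suppression under simulated isoflurane anesthesia.

    Attributes use ASCII transliterations of the conventional symbols:
    ``Gamma_lk`` are the zero-anesthesia PSP peak amplitudes (the model's
    Γ⁰_lk), ``delta_lk`` the PSP rise times, ``N_beta_lk``/``N_alpha_lk``
    intracortical/cortico-cortical synapse counts, ``lambda_ek`` the
    cortico-cortical decay scales and ``v_ek`` the conduction velocities.
    """

    # membrane
    tau_e: float = 65.815        # ms
    tau_i: float = 130.13        # ms
    h_r_e: float = -78.422       # mV
    h_r_i: float = -72.959       # mV
    # firing
    S_max_e: float = 0.39535     # 1/ms
    S_max_i: float = 0.15439     # 1/ms
    mu_e: float = -51.656        # mV
    mu_i: float = -47.267        # mV
    sigma_e: float = 2.8669      # mV
    sigma_i: float = 4.3250      # mV
    # slow synaptic system
    tau_rec_e: float = 800.00    # ms
    tau_rec_i: float = 600.00    # ms
    f_e: float = 1.2500          # dimensionless
    f_i: float = 0.17500         # dimensionless
    # reversal potentials
    h_eq_ee: float = -5.7891     # mV
    h_eq_ei: float = -1.6566     # mV
    h_eq_ie: float = -86.675     # mV
    h_eq_ii: float = -84.596     # mV
    # PSP peak amplitudes at zero anesthesia (Γ⁰_lk)
    Gamma_ee: float = 0.18424    # mV
    Gamma_ei: float = 1.8771     # mV
    Gamma_ie: float = 1.5969     # mV
    Gamma_ii: float = 1.0838     # mV
    # PSP rise times to peak
    delta_ee: float = 9.1059     # ms
    delta_ei: float = 1.2103     # ms
    delta_ie: float = 2.5985     # ms
    delta_ii: float = 9.6946     # ms
    # synapse counts
    N_beta_ee: float = 3410.8
    N_beta_ei: float = 2738.9
    N_beta_ie: float = 863.89
    N_beta_ii: float = 267.92
    N_alpha_ee: float = 3616.3
    N_alpha_ei: float = 2905.1
    # cortico-cortical propagation
    lambda_ee: float = 24.000    # mm
    lambda_ei: float = 24.000    # mm
    v_ee: float = 2.1042         # mm/ms
    v_ei: float = 2.1042         # mm/ms
    # extracortical input rates
    p_ee: float = 9.3193         # 1/ms
    p_ei: float = 3.1563         # 1/ms
    # sigmoid exponent convention: "sqrt2" (default) or "2"
    sigmoid_form: str = "sqrt2"

    # ------------------------------------------------------------------
    def sigmoid_slope(self) -> float:
        """Numerical factor q in S = S_max / (1 + exp(-q (h-mu)/sigma))."""
        if self.sigmoid_form == "sqrt2":
            return 2.0 ** 0.5
        if self.sigmoid_form == "2":
            return 2.0
        raise ValueError(f"unknown sigmoid_form {self.sigmoid_form!r}")

    def cls(self, name: str, lk: str) -> float:
        """Look up a per-class parameter, e.g. ``p.cls('Gamma', 'ie')``."""
        return getattr(self, f"{name}_{lk}")

    def copy(self, **overrides) -> "ModelParams":
        return replace(self, **overrides)


def default_parameters() -> ModelParams:
    """Return the published bursting parameter set (the shipped defaults)."""
    return ModelParams()


def validate(p: ModelParams) -> List[str]:
    """Check parameter invariants; return a list of human-readable violations.

    An empty list means the set is admissible. Diagnostics, not exceptions:
    callers decide whether a violation is fatal.
    """
    v: List[str] = []

    def pos(name):
        if not getattr(p, name) > 0:
            v.append(f"{name} must be strictly positive (got {getattr(p, name)})")

    for name in ("tau_e", "tau_i", "S_max_e", "S_max_i", "sigma_e", "sigma_i",
                 "tau_rec_e", "tau_rec_i", "f_e", "f_i", "p_ee", "p_ei"):
        pos(name)
    for lk in CLASSES:
        pos(f"Gamma_{lk}")
        pos(f"delta_{lk}")
        pos(f"N_beta_{lk}")
    for ek in E_CLASSES:
        pos(f"N_alpha_{ek}")
        pos(f"lambda_{ek}")
        pos(f"v_{ek}")

    # reversal-potential ordering: excitatory above rest, inhibitory below,
    # for both target populations
    for k in ("e", "i"):
        h_r = getattr(p, f"h_r_{k}")
        h_ex = getattr(p, f"h_eq_e{k}")
        h_in = getattr(p, f"h_eq_i{k}")
        if not h_ex > h_r:
            v.append(f"h_eq_e{k} ({h_ex}) must exceed the resting potential "
                     f"h_r_{k} ({h_r})")
        if not h_in < h_r:
            v.append(f"h_eq_i{k} ({h_in}) must lie below the resting potential "
                     f"h_r_{k} ({h_r})")

    if p.sigmoid_form not in ("sqrt2", "2"):
        v.append(f"sigmoid_form must be 'sqrt2' or '2' (got {p.sigmoid_form!r})")
    return v


# ----------------------------------------------------------------------
# serialization

_FIELD_NAMES = [f.name for f in dc_fields(ModelParams)]


def to_yaml(p: ModelParams) -> str:
    """Serialize to a human-editable YAML document with fixed key order."""
    lines = []
    for name in _FIELD_NAMES:
        val = getattr(p, name)
        if isinstance(val, float):
            lines.append(f"{name}: {val!r}")
        else:
            lines.append(f"{name}: {val}")
    return "\n".join(lines) + "\n"


def from_yaml(text: str) -> ModelParams:
    """Parse a parameter document. Unknown keys are an error."""
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("parameter file must be a mapping of name: value")
    unknown = sorted(set(data) - set(_FIELD_NAMES))
    if unknown:
        raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
    return ModelParams(**data)


def save(p: ModelParams, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_yaml(p))


def load(path) -> ModelParams:
    with open(path) as fh:
        return from_yaml(fh.read())
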