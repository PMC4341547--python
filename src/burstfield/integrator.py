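"""Time-stepping driver: grids, concentration protocols, recordings.

The driver advances the full coupled system by forward Euler at a single
Δt (default 0.05 ms) on a toroidal grid, with the damped-wave flux stepped
by its dedicated three-level scheme.  Runs start from the constructed
c = 0 equilibrium, follow a piecewise-linear concentration protocol, and
record selected fields at a decimated rate (default 250 Hz) in single
precision.  Identical (config, seed) pairs produce bit-identical
recordings.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import params as params_mod
from .anesthesia import (MM_PER_MAC, concentration_from_mac,
                         epsilon_from_kappa_vec, hill_excitatory_amplitude,
                         hill_inhibitory_amplitude, inhibitory_decay_factor)
from .equilibrium import construct_initial_state
from .field_dynamics import FieldState, euler_step
from .noise import NoiseGenerator, NoiseSpec
from .params import CLASSES, ModelParams

__all__ = ["Grid", "Segment", "Protocol", "Recording", "run", "step",
           "figure2_protocol", "induction_protocol", "constant_protocol",
           "downsample_tiles", "SimulationDiverged", "anesthetic_tables"]


class SimulationDiverged(RuntimeError):
    """Raised when the state leaves the admissible range or goes non-finite."""


@dataclass(frozen=True)
class Grid:
    """Toroidal simulation grid: nx × ny points at spacing dx (mm)."""

    nx: int
    ny: int
    dx: float = 1.0

    def __post_init__(self):
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid must be at least 8x8")
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def area_cm2(self) -> float:
        return self.nx * self.dx * self.ny * self.dx / 100.0


@dataclass(frozen=True)
class Segment:
    """One protocol segment, linear in concentration; times in seconds."""

    t0: float
    t1: float
    c0: float       # mM
    c1: float       # mM
    label: Optional[str] = None


@dataclass
class Protocol:
    """Contiguous piecewise-linear concentration schedule c(t), t in s."""

    segments: List[Segment]

    def __post_init__(self):
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        prev_end = self.segments[0].t0
        for s in self.segments:
            if s.t1 <= s.t0:
                raise ValueError("segment times must increase")
            if abs(s.t0 - prev_end) > 1e-9:
                raise ValueError("segments must be contiguous")
            if s.c0 < 0 or s.c1 < 0:
                raise ValueError("concentrations must be non-negative")
            prev_end = s.t1
        ts, cs = [self.segments[0].t0], [self.segments[0].c0]
        for s in self.segments:
            ts.append(s.t1)
            cs.append(s.c1)
        self._ts = np.asarray(ts)
        self._cs = np.asarray(cs)

    @property
    def duration_s(self) -> float:
        return float(self.segments[-1].t1)

    @property
    def c_max(self) -> float:
        return float(self._cs.max())

    def c_at(self, t_s):
        """Concentration (mM) at time(s) t in seconds."""
        return np.interp(np.asarray(t_s, dtype=float), self._ts, self._cs)

    def plateaus(self) -> Dict[str, Segment]:
        return {s.label: s for s in self.segments if s.label is not None}

    def to_json(self) -> str:
        return json.dumps([[s.t0, s.t1, s.c0, s.c1, s.label]
                           for s in self.segments])

    @classmethod
    def from_json(cls, text: str) -> "Protocol":
        return cls([Segment(*row) for row in json.loads(text)])


def constant_protocol(c_mM: float, duration_s: float,
                      label: str = "hold") -> Protocol:
    return Protocol([Segment(0.0, duration_s, c_mM, c_mM, label)])


def induction_protocol(plateau_macs: Sequence[float] = (0.0, 0.5, 1.0, 1.5),
                       plateau_s: Sequence[float] = (10.0, 10.0, 40.0, 10.0),
                       ramp_s: Sequence[float] = (10.0, 10.0, 10.0),
                       labels: Sequence[str] = ("C", "D", "E", "F"),
                       final_mac: Optional[float] = 2.5,
                       final_ramp_s: float = 20.0) -> Protocol:
    """Staircase induction: plateaus joined by linear ramps (MAC units)."""
    if len(plateau_s) != len(plateau_macs) or len(ramp_s) != len(plateau_macs) - 1:
        raise ValueError("inconsistent protocol lengths")
    segs: List[Segment] = []
    t = 0.0
    for i, (mac, dur) in enumerate(zip(plateau_macs, plateau_s)):
        c = concentration_from_mac(mac)
        segs.append(Segment(t, t + dur, c, c, labels[i]))
        t += dur
        if i < len(plateau_macs) - 1:
            c_next = concentration_from_mac(plateau_macs[i + 1])
            segs.append(Segment(t, t + ramp_s[i], c, c_next, None))
            t += ramp_s[i]
    if final_mac is not None:
        c_last = concentration_from_mac(plateau_macs[-1])
        segs.append(Segment(t, t + final_ramp_s, c_last,
                            concentration_from_mac(final_mac), None))
    return Protocol(segs)


def figure2_protocol() -> Protocol:
    """The standard 120 s induction staircase 0 → 2.5 MAC.

    Plateaus C (0 MAC, 10 s), D (0.5 MAC, 10 s), E (1.0 MAC, 40 s) and
    F (1.5 MAC, 10 s), joined by 10 s linear ramps, with a final 20 s ramp
    to 2.5 MAC.  The ramp up to 1.0 MAC is taken as 10 s like the others.
    """
    return induction_protocol()


# ----------------------------------------------------------------------
# recordings

@dataclass
class Recording:
    """Decimated time series of selected fields plus run metadata.

    ``fields`` maps name → float32 array (nt, ny, nx).  ``t`` is in
    seconds, ``c`` the concentration (mM) at each frame.  ``gamma_ee()``
    reconstructs the effective excitatory peak amplitude
    Γ_ee(t) = Γ⁰_ee · C_e · H_e(c) from the recorded efficacy.
    """

    t: np.ndarray
    c: np.ndarray
    fields: Dict[str, np.ndarray]
    fs_hz: float
    grid: Grid
    params: ModelParams
    protocol: Protocol
    seed: int
    dt_ms: float
    final_state: Optional[FieldState] = None
    S0: Optional[Tuple[float, float]] = None

    def gamma_ee(self) -> np.ndarray:
        """Effective Γ_ee(t, x) in mV (nt, ny, nx) from C_e and c(t)."""
        if "C_e" not in self.fields:
            raise KeyError("recording does not contain C_e")
        H = hill_excitatory_amplitude(self.c).astype(np.float32)
        return (self.params.Gamma_ee * self.fields["C_e"]
                * H[:, None, None])

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Frame indices with t0 <= t < t1 (seconds)."""
        return np.where((self.t >= t0 - 1e-9) & (self.t < t1 - 1e-9))[0]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("t", data=self.t)
            h5.create_dataset("c", data=self.c)
            for name, arr in self.fields.items():
                h5.create_dataset(f"fields/{name}", data=arr)
            h5.attrs["fs_hz"] = self.fs_hz
            h5.attrs["dt_ms"] = self.dt_ms
            h5.attrs["seed"] = self.seed
            h5.attrs["grid"] = json.dumps([self.grid.nx, self.grid.ny, self.grid.dx])
            h5.attrs["params"] = params_mod.to_yaml(self.params)
            h5.attrs["protocol"] = self.protocol.to_json()
            if self.S0 is not None:
                h5.attrs["S0"] = json.dumps(list(self.S0))

    @classmethod
    def load(cls, path) -> "Recording":
        import h5py

        with h5py.File(path, "r") as h5:
            nx, ny, dx = json.loads(h5.attrs["grid"])
            S0 = tuple(json.loads(h5.attrs["S0"])) if "S0" in h5.attrs else None
            return cls(
                t=h5["t"][:], c=h5["c"][:],
                fields={k: h5["fields"][k][:] for k in h5["fields"]},
                fs_hz=float(h5.attrs["fs_hz"]), dt_ms=float(h5.attrs["dt_ms"]),
                seed=int(h5.attrs["seed"]),
                grid=Grid(int(nx), int(ny), float(dx)),
                params=params_mod.from_yaml(h5.attrs["params"]),
                protocol=Protocol.from_json(h5.attrs["protocol"]),
                S0=S0)


def downsample_tiles(frames: np.ndarray, tile: int = 4) -> np.ndarray:
    """Average non-overlapping tile × tile blocks of the trailing two axes."""
    ny, nx = frames.shape[-2:]
    if ny % tile or nx % tile:
        raise ValueError("grid dimensions must be divisible by the tile size")
    shape = frames.shape[:-2] + (ny // tile, tile, nx // tile, tile)
    return frames.reshape(shape).mean(axis=(-3, -1))


# ----------------------------------------------------------------------
# per-concentration scalar tables

def anesthetic_tables(p: ModelParams, c_max: float, n: int = 513):
    """Per-class (γ, γ̃, gain) sampled on a concentration grid [0, c_max].

    Linear interpolation on these tables supplies the per-substep scalars
    during ramps; plateau concentrations should coincide with the c = 0
    node or are interpolated to ~1e-7 relative accuracy.
    """
    cs = np.linspace(0.0, max(c_max, 1e-12), n)
    He = hill_excitatory_amplitude(cs)
    Hi = hill_inhibitory_amplitude(cs)
    eps_i = epsilon_from_kappa_vec(inhibitory_decay_factor(cs))
    gam = np.empty((n, 4))
    gtil = np.empty((n, 4))
    gain = np.empty((n, 4))
    for m, lk in enumerate(CLASSES):
        d = p.cls("delta", lk)
        G0 = p.cls("Gamma", lk)
        if lk[0] == "e":
            gam[:, m] = 1.0 / d
            gtil[:, m] = 1.0 / d
            gain[:, m] = np.e * G0 * He * d
        else:
            g = np.where(eps_i < 1e-8, (1.0 - 0.5 * eps_i) / d,
                         eps_i / np.expm1(np.maximum(eps_i, 1e-8)) / d)
            gam[:, m] = g
            gtil[:, m] = np.exp(eps_i) * g
            gain[:, m] = np.exp(g * d) * G0 * Hi / g
    return cs, gam, gtil, gain


# ----------------------------------------------------------------------
# the driver

def _as_map(val, shape) -> np.ndarray:
    out = np.empty(shape)
    out[...] = val
    return out


def step(state: FieldState, p: ModelParams, sp, anes, p_ee_field,
         dx: float, dt: float, freeze_C: bool = False) -> FieldState:
    """Single reference forward-Euler step (thin re-export for convenience)."""
    return euler_step(state, p, anes, sp, p_ee_field, dx, dt, freeze_C)


def run(p: ModelParams, grid: Grid, protocol: Protocol,
        noise_spec: Optional[NoiseSpec] = None, *,
        dt_ms: float = 0.05, fs_hz: float = 250.0, seed: int = 0,
        freeze_C: bool = False,
        f_e_map=None, f_i_map=None,
        backend: str = "numba", keep_final_state: bool = True,
        check_interval_s: float = 0.25, progress: bool = False) -> Recording:
    """Simulate the protocol from the constructed c = 0 equilibrium.

    Records h_e and C_e at ``fs_hz`` in single precision.  ``backend`` is
    "numba" (production) or "reference" (plain numpy, identical math, for
    cross-validation at small sizes).  Raises SimulationDiverged if the
    state leaves the admissible range.
    """
    violations = params_mod.validate(p)
    if violations:
        raise ValueError("invalid parameters: " + "; ".join(violations))
    if noise_spec is None:
        noise_spec = NoiseSpec(mean=p.p_ee)

    ny, nx = grid.shape
    rec_every_f = 1000.0 / fs_hz / dt_ms
    rec_every = int(round(rec_every_f))
    if abs(rec_every - rec_every_f) > 1e-9:
        raise ValueError("sample rate must divide the step rate evenly")
    n_steps = int(round(protocol.duration_s * 1000.0 / dt_ms))
    n_rec = (n_steps + rec_every - 1) // rec_every

    fe = _as_map(p.f_e if f_e_map is None else f_e_map, (ny, nx))
    fi = _as_map(p.f_i if f_i_map is None else f_i_map, (ny, nx))
    state, sp, eq = construct_initial_state(p, (ny, nx), f_e=fe, f_i=fi)

    gen = NoiseGenerator(noise_spec, (ny, nx), grid.dx, dt_ms, seed)
    cs_tab, gam_tab, gtil_tab, gain_tab = anesthetic_tables(p, protocol.c_max)

    # flat per-class constants
    heq = np.array([p.cls("h_eq", lk) for lk in CLASSES])
    h_r = {"e": p.h_r_e, "i": p.h_r_i}
    psid = np.array([1.0 / abs(p.cls("h_eq", lk) - h_r[lk[1]]) for lk in CLASSES])
    Nb = np.array([p.cls("N_beta", lk) for lk in CLASSES])
    Na = np.array([p.N_alpha_ee, p.N_alpha_ei])
    nphi = state.phi.shape[0]
    phi_classes = ["ee"] if nphi == 1 else ["ee", "ei"]
    lam = np.array([p.cls("lambda", lk) for lk in phi_classes])
    vel = np.array([p.cls("v", lk) for lk in phi_classes])
    q = p.sigmoid_slope()

    I_arr = np.stack([state.I[lk] for lk in CLASSES])
    J_arr = np.stack([state.J[lk] for lk in CLASSES])
    he, hi_ = state.h_e, state.h_i
    phi, phi_prev = state.phi, state.phi_prev
    Ce, Ci = state.C_e, state.C_i
    phi_new = np.empty_like(phi)
    Se_buf = np.empty((ny, nx))
    Si_buf = np.empty((ny, nx))
    src_buf = np.empty((ny, nx))

    rec_he = np.empty((n_rec, ny, nx), dtype=np.float32)
    rec_ce = np.empty((n_rec, ny, nx), dtype=np.float32)

    h_lo = heq.min() - 10.0
    h_hi = heq.max() + 10.0
    c_cap_e = 1.0 + fe + 1e-6
    c_cap_i = 1.0 + fi + 1e-6
    check_every = max(1, int(round(check_interval_s * 1000.0 / dt_ms)))
    next_check = check_every

    if backend == "numba":
        from ._kernel import advance_chunk
    elif backend != "reference":
        raise ValueError("backend must be 'numba' or 'reference'")

    t_wall = time.time()
    step0 = 0
    while step0 < n_steps:
        kb = gen.knot_steps - (step0 % gen.knot_steps)
        K = min(kb, n_steps - step0)
        k0, k1, k2, k3, wts = gen.chunk(step0, K)
        gsteps = step0 + np.arange(K)
        c_sub = protocol.c_at(gsteps * dt_ms / 1000.0)
        gam = np.stack([np.interp(c_sub, cs_tab, gam_tab[:, m]) for m in range(4)], axis=1)
        gtil = np.stack([np.interp(c_sub, cs_tab, gtil_tab[:, m]) for m in range(4)], axis=1)
        gain = np.stack([np.interp(c_sub, cs_tab, gain_tab[:, m]) for m in range(4)], axis=1)
        rec_slot = np.where(gsteps % rec_every == 0, gsteps // rec_every,
                            -1).astype(np.int64)

        if backend == "numba":
            advance_chunk(he, hi_, I_arr, J_arr, phi, phi_prev, phi_new,
                          Ce, Ci, fe, fi, k0, k1, k2, k3, wts,
                          gam, gtil, gain, rec_slot, rec_he, rec_ce,
                          dt_ms, grid.dx, p.tau_e, p.tau_i, p.h_r_e, p.h_r_i,
                          heq, psid, Nb, Na, noise_spec.mean, p.p_ei,
                          p.S_max_e, p.S_max_i, p.mu_e, p.mu_i,
                          q / p.sigma_e, q / p.sigma_i,
                          sp.S0_e, sp.S0_i, p.tau_rec_e, p.tau_rec_i,
                          lam, vel, state.phi_index["ee"],
                          state.phi_index["ei"], freeze_C,
                          Se_buf, Si_buf, src_buf)
        else:
            ref = FieldState(h_e=he, h_i=hi_,
                             I={lk: I_arr[m] for m, lk in enumerate(CLASSES)},
                             J={lk: J_arr[m] for m, lk in enumerate(CLASSES)},
                             phi=phi, phi_prev=phi_prev, C_e=Ce, C_i=Ci,
                             phi_index=state.phi_index)
            for s in range(K):
                if rec_slot[s] >= 0:
                    rec_he[rec_slot[s]] = ref.h_e.astype(np.float32)
                    rec_ce[rec_slot[s]] = ref.C_e.astype(np.float32)
                anes = SimpleNamespace(
                    gamma={lk: gam[s, m] for m, lk in enumerate(CLASSES)},
                    gamma_tilde={lk: gtil[s, m] for m, lk in enumerate(CLASSES)},
                    gain=lambda pp, lk, _s=s: gain[_s, CLASSES.index(lk)])
                p_field = (noise_spec.mean
                           + wts[s, 0] * k0 + wts[s, 1] * k1
                           + wts[s, 2] * k2 + wts[s, 3] * k3)
                ref = euler_step(ref, p, anes, sp, p_field, grid.dx, dt_ms,
                                 freeze_C)
            he, hi_ = ref.h_e, ref.h_i
            for m, lk in enumerate(CLASSES):
                I_arr[m] = ref.I[lk]
                J_arr[m] = ref.J[lk]
            phi, phi_prev = ref.phi, ref.phi_prev
            Ce, Ci = ref.C_e, ref.C_i

        step0 += K
        if step0 >= next_check or step0 >= n_steps:
            next_check += check_every
            if not (np.all(np.isfinite(he)) and np.all(np.isfinite(hi_))):
                raise SimulationDiverged(
                    f"non-finite membrane potential at t = {step0 * dt_ms / 1000.0:.3f} s")
            if he.min() < h_lo or he.max() > h_hi or hi_.min() < h_lo or hi_.max() > h_hi:
                raise SimulationDiverged(
                    f"membrane potential outside [{h_lo:.1f}, {h_hi:.1f}] mV "
                    f"at t = {step0 * dt_ms / 1000.0:.3f} s")
            if Ce.min() <= 0 or Ci.min() <= 0 or np.any(Ce > c_cap_e) or np.any(Ci > c_cap_i):
                raise SimulationDiverged(
                    f"synaptic efficacy outside (0, 1+f] at t = {step0 * dt_ms / 1000.0:.3f} s")
            if progress:
                done = step0 / n_steps
                print(f"  t = {step0 * dt_ms / 1000.0:7.2f} s "
                      f"({100 * done:5.1f} %), wall {time.time() - t_wall:7.1f} s",
                      flush=True)

    t_frames = np.arange(n_rec) * rec_every * dt_ms / 1000.0
    final = FieldState(h_e=he, h_i=hi_,
                       I={lk: I_arr[m] for m, lk in enumerate(CLASSES)},
                       J={lk: J_arr[m] for m, lk in enumerate(CLASSES)},
                       phi=phi, phi_prev=phi_prev, C_e=Ce, C_i=Ci,
                       phi_index=state.phi_index) if keep_final_state else None
    return Recording(t=t_frames, c=protocol.c_at(t_frames),
                     fields={"h_e": rec_he, "C_e": rec_ce},
                     fs_hz=fs_hz, grid=grid, params=p, protocol=protocol,
                     seed=seed, dt_ms=dt_ms, final_state=final,
                     S0=(sp.S0_e, sp.S0_i))
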