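"""Reproducible run configurations for the three study experiments.

Each experiment exists at two scales:

* ``"paper"`` — the full-scale configuration (512 × 512 grid at 1 mm,
  full protocol durations).  These are cluster-sized runs; expect hours
  on one CPU.
* ``"desk"`` — reduced configurations sized for a workstation, chosen to
  preserve the property each experiment probes: the induction run keeps
  the plateau staircase but shortens the bursting plateau; the patch run
  keeps the printed patch radius of 9.6 cm = 4λ and the standard λ = 2.4
  cm but coarsens to Δx = 2 mm on a 25.6 cm torus; the connectivity-scale
  sweep keeps shared noise seeds across λ values on a 6.4 cm torus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .analysis import (BurstStats, PSDResult, detect_burst_peaks,
                       grid_average_psd, ibi_statistics, total_power_ratio)
from .integrator import (Grid, Protocol, Recording, constant_protocol,
                         figure2_protocol, induction_protocol, run)
from .params import ModelParams, default_parameters

__all__ = ["PatchSpec", "patch_mask", "run_figure2", "run_lambda_sweep",
           "run_patch_experiment", "Figure2Result", "LambdaSweepResult",
           "PatchResult", "pattern_correlation_length"]

LAMBDA_SWEEP_CM = (2.7, 2.4, 2.1)
PATCH_CONCENTRATION_MM = 0.25


# ----------------------------------------------------------------------
# patch geometry

@dataclass(frozen=True)
class PatchSpec:
    """Circular override region on the torus (closed disk).

    Coordinates and radius in cm; ``inside``/``outside`` are the values of
    the overridden per-point parameter (the inhibitory depletion factor
    f_i in the study experiment).
    """

    center_cm: Tuple[float, float] = (20.0, 20.0)
    radius_cm: float = 9.6
    inside: float = 1.25
    outside: float = 0.175

    def __post_init__(self):
        if self.radius_cm <= 0:
            raise ValueError("patch radius must be positive")


def _toroidal_distance_mm(grid: Grid, center_cm) -> np.ndarray:
    cy, cx = center_cm[1] * 10.0, center_cm[0] * 10.0
    y = np.arange(grid.ny) * grid.dx
    x = np.arange(grid.nx) * grid.dx
    Ly, Lx = grid.ny * grid.dx, grid.nx * grid.dx
    dy = np.abs(y - cy)
    dy = np.minimum(dy, Ly - dy)[:, None]
    dxv = np.abs(x - cx)
    dxv = np.minimum(dxv, Lx - dxv)[None, :]
    return np.hypot(dy, dxv)


def patch_mask(spec: PatchSpec, grid: Grid) -> np.ndarray:
    """Per-point override map: inside value on the closed disk, else outside."""
    if 2.0 * spec.radius_cm * 10.0 > min(grid.nx, grid.ny) * grid.dx:
        raise ValueError("patch does not fit on the torus")
    dist = _toroidal_distance_mm(grid, spec.center_cm)
    return np.where(dist <= spec.radius_cm * 10.0, spec.inside, spec.outside)


# ----------------------------------------------------------------------
# induction experiment

@dataclass
class Figure2Result:
    recording: Recording
    psds: Dict[str, PSDResult]
    power_ratios: Dict[str, float]        # vs plateau C
    bursts: Dict[str, BurstStats]

    @property
    def bursting_plateaus(self) -> List[str]:
        return [lab for lab, bs in self.bursts.items()
                if bs.fraction_bursting > 0.5]


def _figure2_config(scale: str) -> Tuple[Grid, Protocol]:
    if scale == "paper":
        return Grid(512, 512, 1.0), figure2_protocol()
    if scale == "desk":
        # full staircase with a 15 s bursting plateau and no final ramp
        return (Grid(64, 64, 1.0),
                induction_protocol(plateau_s=(10.0, 10.0, 15.0, 10.0),
                                   final_mac=None))
    raise ValueError("scale must be 'paper' or 'desk'")


def run_figure2(scale: str = "desk", seed: int = 0,
                p: Optional[ModelParams] = None,
                progress: bool = False) -> Figure2Result:
    """Anesthesia induction staircase with per-plateau PSDs and bursts.

    Emits grid-averaged plateau spectra, total-power ratios relative to
    the awake plateau C, and burst statistics per plateau.  At desk scale
    bursting is expected only on plateau E (1 MAC).
    """
    p = p or default_parameters()
    grid, protocol = _figure2_config(scale)
    rec = run(p, grid, protocol, seed=seed, progress=progress)
    psds, ratios, bursts = {}, {}, {}
    for lab, seg in protocol.plateaus().items():
        psds[lab] = grid_average_psd(rec, lab)
        bursts[lab] = ibi_statistics(rec, (seg.t0, seg.t1))
    for lab in psds:
        ratios[lab] = psds[lab].total_power / psds["C"].total_power
    return Figure2Result(recording=rec, psds=psds, power_ratios=ratios,
                         bursts=bursts)


# ----------------------------------------------------------------------
# connectivity-scale sweep

@dataclass
class LambdaSweepResult:
    lambdas_cm: Tuple[float, ...]
    recordings: Dict[float, Recording]
    stats: Dict[float, BurstStats]
    correlation_length_mm: Dict[float, float]


def pattern_correlation_length(frames: np.ndarray, dx_mm: float) -> float:
    """Spatial autocorrelation length (mm) of mean-removed field frames.

    FFT autocorrelation averaged over frames, radially binned; returns the
    first radius where the normalised correlation falls below 1/e.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    ny, nx = frames.shape[-2:]
    acc = np.zeros((ny, nx))
    for fr in frames:
        z = fr - fr.mean()
        F = np.fft.fft2(z)
        acc += np.fft.ifft2(F * np.conj(F)).real
    acc /= acc[0, 0]
    iy = np.minimum(np.arange(ny), ny - np.arange(ny))[:, None]
    ix = np.minimum(np.arange(nx), nx - np.arange(nx))[None, :]
    r = np.hypot(iy, ix) * dx_mm
    rb = np.arange(0.0, r.max(), dx_mm)
    prof = np.array([acc[(r >= a) & (r < a + dx_mm)].mean() for a in rb])
    below = np.where(prof < np.exp(-1.0))[0]
    if len(below) == 0:
        return float(rb[-1])
    i = below[0]
    return float(rb[i]) if i == 0 else float(
        rb[i - 1] + dx_mm * (prof[i - 1] - np.exp(-1.0)) / (prof[i - 1] - prof[i]))


def run_lambda_sweep(lambdas_cm: Sequence[float] = LAMBDA_SWEEP_CM,
                     scale: str = "desk", seed: int = 0,
                     p: Optional[ModelParams] = None,
                     progress: bool = False) -> LambdaSweepResult:
    """Burst statistics vs the cortico-cortical decay scale λ_ek.

    All λ values run with the identical noise stream (same seed and grid)
    so that orderings are not noise artifacts.  Desk scale: 64 × 64 grid
    at 1 mm, 20 s at 0.25 mM with a 4 s discarded transient.
    """
    p = p or default_parameters()
    if scale == "paper":
        grid, dur, t0 = Grid(512, 512, 1.0), 55.0, 5.0
    elif scale == "desk":
        grid, dur, t0 = Grid(64, 64, 1.0), 20.0, 4.0
    else:
        raise ValueError("scale must be 'paper' or 'desk'")
    protocol = constant_protocol(PATCH_CONCENTRATION_MM, dur)
    recs, stats, corr = {}, {}, {}
    for lam in lambdas_cm:
        pl = p.copy(lambda_ee=lam * 10.0, lambda_ei=lam * 10.0)
        rec = run(pl, grid, protocol, seed=seed, progress=progress)
        recs[lam] = rec
        stats[lam] = ibi_statistics(rec, (t0, dur))
        w = rec.window(t0, dur)
        corr[lam] = pattern_correlation_length(
            rec.fields["h_e"][w[:: max(1, len(w) // 16)]], grid.dx)
    return LambdaSweepResult(lambdas_cm=tuple(lambdas_cm), recordings=recs,
                             stats=stats, correlation_length_mm=corr)


# ----------------------------------------------------------------------
# heterogeneous patch experiment

@dataclass
class ProbeResult:
    name: str
    iy: int
    ix: int
    distance_mm: float
    peak_times: np.ndarray
    h_e_sd: float
    gamma_ee_min: float


@dataclass
class PatchResult:
    recording: Recording
    spec: PatchSpec
    probes: Dict[str, ProbeResult]
    analysis_window: Tuple[float, float]


def run_patch_experiment(scale: str = "desk", f_i_inside: float = 1.25,
                         seed: int = 0, p: Optional[ModelParams] = None,
                         progress: bool = False) -> PatchResult:
    """Circular f_i-heterogeneity patch at 0.25 mM isoflurane.

    The patch keeps the printed radius 9.6 cm = 4λ so that cortico-
    cortical influence from outside decays to < e⁻⁴ ≈ 2 % at the centre.
    Desk scale coarsens to Δx = 2 mm on a 25.6 cm torus (the patch then
    covers 44 % of the sheet, against 11 % at full scale, which makes the
    rim spill-in relatively stronger but preserves the centre/rim/outside
    distinction).  Probes: patch centre, rim (radius − λ from centre) and
    the antipodal outside point.
    """
    p = p or default_parameters()
    if scale == "paper":
        grid, dur, window = Grid(512, 512, 1.0), 50.0, (10.0, 50.0)
        spec = PatchSpec(center_cm=(20.0, 20.0), inside=f_i_inside,
                         outside=p.f_i)
    elif scale == "desk":
        grid, dur, window = Grid(128, 128, 2.0), 22.0, (10.0, 22.0)
        spec = PatchSpec(center_cm=(12.8, 12.8), inside=f_i_inside,
                         outside=p.f_i)
    else:
        raise ValueError("scale must be 'paper' or 'desk'")

    fimap = patch_mask(spec, grid)
    protocol = constant_protocol(PATCH_CONCENTRATION_MM, dur)
    rec = run(p, grid, protocol, seed=seed, f_i_map=fimap, progress=progress)

    dist = _toroidal_distance_mm(grid, spec.center_cm)
    cy = int(round(spec.center_cm[1] * 10.0 / grid.dx)) % grid.ny
    cx = int(round(spec.center_cm[0] * 10.0 / grid.dx)) % grid.nx
    rim_off = int(round((spec.radius_cm * 10.0 - p.lambda_ee) / grid.dx))
    probes_ix = {
        "center": (cy, cx),
        "rim": (cy, (cx + rim_off) % grid.nx),
        "outside": ((cy + grid.ny // 2) % grid.ny, (cx + grid.nx // 2) % grid.nx),
    }
    ge = rec.gamma_ee()
    w = rec.window(*window)
    tt = rec.t[w]
    probes = {}
    for name, (iy, ix) in probes_ix.items():
        tr = ge[w, iy, ix].astype(float)
        he = rec.fields["h_e"][w, iy, ix].astype(float)
        probes[name] = ProbeResult(
            name=name, iy=iy, ix=ix, distance_mm=float(dist[iy, ix]),
            peak_times=detect_burst_peaks(tt, tr),
            h_e_sd=float(he.std()), gamma_ee_min=float(tr.min()))
    return PatchResult(recording=rec, spec=spec, probes=probes,
                       analysis_window=window)
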