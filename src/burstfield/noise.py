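"""Spatiotemporally filtered stochastic extracortical drive p_ee(x, t).

Independent Gaussian knot fields are drawn on the grid at a regular knot
interval, lowpass-filtered in the spatial Fourier domain (radially
symmetric Gaussian transfer, calibrated to -3 dB at the requested spatial
frequency), and interpolated in time with a Catmull-Rom spline whose knot
spacing is calibrated so that the interpolated process has its -3 dB point
at the requested temporal cutoff.  A final variance renormalisation makes
the long-run per-point standard deviation equal to ``relative_sd * mean``
regardless of the filter settings.

The stream is fully determined by (spec, grid shape, dx, dt, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

__all__ = ["NoiseSpec", "NoiseGenerator", "psd_of_stream",
           "catmull_rom_weights"]


def _keys_kernel(u):
    """Catmull-Rom (Keys, a = -1/2) interpolation kernel, support [-2, 2]."""
    au = np.abs(np.asarray(u, dtype=float))
    out = np.where(au <= 1.0, 1.5 * au ** 3 - 2.5 * au ** 2 + 1.0,
                   np.where(au <= 2.0, -0.5 * au ** 3 + 2.5 * au ** 2 - 4.0 * au + 2.0,
                            0.0))
    return out


def catmull_rom_weights(u: float) -> np.ndarray:
    """Weights on knots (n-1, n, n+1, n+2) for fractional position u in [0,1)."""
    return _keys_kernel(np.array([u + 1.0, u, u - 1.0, u - 2.0]))


@lru_cache(maxsize=1)
def _kernel_half_power_freq() -> float:
    """Dimensionless -3 dB frequency ν_c of Catmull-Rom knot interpolation.

    The interpolated process x(t) = Σ z_n K(t/h - n) of unit white knots
    has spectrum ∝ |K̂(f h)|²; ν_c solves |K̂(ν)|² = 1/2 (K̂(0) = 1).
    """
    u = np.linspace(0.0, 2.0, 4001)
    k = _keys_kernel(u)

    def khat(nu):
        return 2.0 * np.trapezoid(k * np.cos(2.0 * np.pi * nu * u), u)

    return brentq(lambda nu: khat(nu) ** 2 - 0.5, 1e-3, 0.5, xtol=1e-10)


@lru_cache(maxsize=1)
def _interp_variance_factor() -> float:
    """Time-averaged variance of the interpolant of unit-variance knots."""
    us = np.linspace(0.0, 1.0, 2001)
    w2 = np.array([np.sum(catmull_rom_weights(u) ** 2) for u in us])
    return float(np.trapezoid(w2, us))


@dataclass
class NoiseSpec:
    """Statistical specification of the p_ee drive.

    mean in 1/ms (the model's p_ee); relative_sd dimensionless; temporal
    cutoff in Hz (-3 dB of the per-point spectrum); spatial cutoff in
    cycles/cm (-3 dB of the spatial power transfer).
    """

    mean: float
    relative_sd: float = 0.10
    temporal_cutoff_hz: float = 75.0
    spatial_cutoff_per_cm: float = 2.0

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("noise mean must be positive")
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be non-negative")
        if self.temporal_cutoff_hz <= 0 or self.spatial_cutoff_per_cm <= 0:
            raise ValueError("cutoffs must be positive")


class NoiseGenerator:
    """Deterministic, seekable-forward generator of the filtered p_ee field.

    ``field_at(step)`` returns the field at global step index ``step`` (must
    be called with non-decreasing knot demand); ``chunk(step0, n)`` returns
    the four knot fields and per-substep weights covering steps
    [step0, step0+n), which is what the compiled stepper consumes.
    """

    def __init__(self, spec: NoiseSpec, shape, dx_mm: float, dt_ms: float,
                 seed: int):
        self.spec = spec
        self.shape = tuple(shape)
        self.dx = float(dx_mm)
        self.dt = float(dt_ms)
        self.rng = np.random.default_rng(seed)

        # temporal calibration: knot interval h with ν_c / h = cutoff
        cutoff_per_ms = spec.temporal_cutoff_hz / 1000.0
        h_ms = _kernel_half_power_freq() / cutoff_per_ms
        self.knot_steps = max(1, int(round(h_ms / self.dt)))

        # spatial transfer |T|² = 2^-(k/k_c)², -3 dB at k_c (cycles/mm)
        k_c = spec.spatial_cutoff_per_cm / 10.0
        ny, nx = self.shape
        ky = np.fft.fftfreq(ny, d=self.dx)[:, None]
        kx = np.fft.fftfreq(nx, d=self.dx)[None, :]
        k2 = kx ** 2 + ky ** 2
        self._T = np.exp(-0.5 * np.log(2.0) * k2 / k_c ** 2)
        if np.max(np.abs(kx)) < k_c or np.max(np.abs(ky)) < k_c:
            warnings.warn("grid too coarse to resolve the spatial noise "
                          "cutoff; the field will be nearly white in space")
        # per-point variance after the spatial filter (Parseval)
        self._spatial_var = float(np.mean(self._T ** 2))
        self.amp = (spec.relative_sd * spec.mean
                    / np.sqrt(_interp_variance_factor()))

        self._knots: list[np.ndarray] = []
        self._base = 0           # knot index of self._knots[0]
        self._initialized = False

    # ------------------------------------------------------------------
    def _fresh_knot(self) -> np.ndarray:
        white = self.rng.standard_normal(self.shape)
        f = np.fft.ifft2(np.fft.fft2(white) * self._T).real
        return f / np.sqrt(self._spatial_var)

    def _ensure_knots(self, upto: int) -> None:
        """Make knots with indices up to ``upto`` available (monotone)."""
        if not self._initialized:
            self._knots = [self._fresh_knot() for _ in range(4)]
            self._base = -1      # knots -1, 0, 1, 2
            self._initialized = True
        while self._base + len(self._knots) - 1 < upto:
            self._knots.append(self._fresh_knot())
        # drop knots that can never be needed again (keep a window of 8)
        drop = len(self._knots) - 8
        if drop > 0 and self._base + drop <= upto - 3:
            self._knots = self._knots[drop:]
            self._base += drop

    def _knot(self, idx: int) -> np.ndarray:
        return self._knots[idx - self._base]

    def chunk(self, step0: int, n: int):
        """Knot fields and weights for steps [step0, step0+n).

        The chunk must lie within one knot interval.  Returns
        (k0, k1, k2, k3, wts) with wts of shape (n, 4), already scaled by
        the calibrated amplitude, such that
        p_ee(step) = mean + Σ_j wts[s, j] * k_j.
        """
        m = step0 // self.knot_steps
        if (step0 + n - 1) // self.knot_steps != m:
            raise ValueError("chunk crosses a knot boundary")
        self._ensure_knots(m + 2)
        if self.spec.relative_sd == 0.0:
            wts = np.zeros((n, 4))
        else:
            us = ((np.arange(step0, step0 + n) % self.knot_steps)
                  / self.knot_steps)
            wts = self.amp * np.stack([catmull_rom_weights(u) for u in us])
        return (self._knot(m - 1), self._knot(m), self._knot(m + 1),
                self._knot(m + 2), wts)

    def field_at(self, step: int) -> np.ndarray:
        """p_ee field at a global step (reference path, one step at a time)."""
        if self.spec.relative_sd == 0.0:
            return np.full(self.shape, self.spec.mean)
        m, r = divmod(step, self.knot_steps)
        self._ensure_knots(m + 2)
        w = self.amp * catmull_rom_weights(r / self.knot_steps)
        out = np.full(self.shape, self.spec.mean)
        for j, kidx in enumerate(range(m - 1, m + 3)):
            out += w[j] * self._knot(kidx)
        return out


def psd_of_stream(spec: NoiseSpec, dt_ms: float, duration_s: float,
                  seed: int = 0, sample_every: int = 10, shape=(8, 8),
                  dx_mm: float = 1.0):
    """Temporal PSD of a single grid point of the generated stream.

    Returns (frequencies_hz, density).  Diagnostic used to verify the
    -3 dB temporal calibration.
    """
    from scipy.signal import welch

    gen = NoiseGenerator(spec, shape, dx_mm, dt_ms, seed)
    n = int(round(duration_s * 1000.0 / dt_ms))
    steps = np.arange(0, n, sample_every)
    trace = np.empty(len(steps))
    for i, s in enumerate(steps):
        trace[i] = gen.field_at(int(s))[0, 0]
    fs_hz = 1000.0 / (dt_ms * sample_every)
    f, pxx = welch(trace, fs=fs_hz, nperseg=min(len(trace), 8192))
    return f, pxx


def measure_minus3db_hz(f: np.ndarray, pxx: np.ndarray,
                        plateau_band=(5.0, 40.0)) -> float:
    """First frequency where the PSD falls to half its low-frequency plateau."""
    sel = (f >= plateau_band[0]) & (f <= plateau_band[1])
    plateau = float(np.mean(pxx[sel]))
    above = f > plateau_band[1]
    idx = np.where(above & (pxx < 0.5 * plateau))[0]
    if len(idx) == 0:
        raise RuntimeError("PSD never fell below half the plateau")
    i = idx[0]
    # linear interpolation across the crossing bin
    f0, f1 = f[i - 1], f[i]
    p0, p1 = pxx[i - 1], pxx[i]
    frac = (0.5 * plateau - p0) / (p1 - p0)
    return float(f0 + frac * (f1 - f0))
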