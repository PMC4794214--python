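"""2D Gabor fits to subunit receptive-field halves and per-model probe params.

Each learned subunit filter has a left-eye and a right-eye half; fitting a
Gabor to every non-degenerate half yields carrier frequency and orientation
estimates, whose per-model means set the sine-grating probe used downstream.
Gabor fitting is multimodal, so the fit is initialised from the discrete
Fourier peak (frequency, orientation) and the centroid of the squared field,
then refined by bounded nonlinear least squares with a handful of restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["GaborParams", "ProbeParams", "fit_gabor", "model_probe_params",
           "circular_mean_orientation"]


@dataclass
class GaborParams:
    amplitude: float = 0.0
    x0: float = 0.0
    y0: float = 0.0
    sigma_par: float = 1.0
    sigma_orth: float = 1.0
    frequency: float = 0.0   # cycles / px along the carrier direction
    orientation: float = 0.0  # radians in [0, pi)
    phase: float = 0.0
    offset: float = 0.0
    goodness: float = 0.0    # 1 - SSE / sum(field**2), in [0, 1]
    degenerate: bool = False


@dataclass
class ProbeParams:
    """Per-model sine-grating probe: mean frequency, circular-mean orientation."""

    frequency: float
    orientation: float

    @property
    def wavelength(self) -> float:
        return 1.0 / self.frequency


def _gabor_values(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    amp, x0, y0, s_par, s_orth, freq, theta, phase, offset = params
    u = (x - x0) * np.cos(theta) + (y - y0) * np.sin(theta)
    v = -(x - x0) * np.sin(theta) + (y - y0) * np.cos(theta)
    env = np.exp(-(u ** 2) / (2 * s_par ** 2) - (v ** 2) / (2 * s_orth ** 2))
    return amp * env * np.cos(2 * np.pi * freq * u + phase) + offset


def _fft_init(field: np.ndarray) -> tuple[float, float]:
    """Frequency and orientation of the dominant Fourier component."""
    p = field.shape[0]
    spec = np.abs(np.fft.fft2(field))
    spec[0, 0] = 0.0
    ky, kx = np.unravel_index(np.argmax(spec), spec.shape)
    fy = np.fft.fftfreq(p)[ky]
    fx = np.fft.fftfreq(p)[kx]
    freq = float(np.hypot(fx, fy))
    theta = float(math.atan2(fy, fx))
    if freq < 0.5 / p:
        freq = 1.0 / p
    return freq, theta


def _phase_init(field, freq, theta, x, y, cx, cy) -> float:
    u = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)
    c = float(np.sum(field * np.cos(2 * np.pi * freq * u)))
    s = float(np.sum(field * np.sin(2 * np.pi * freq * u)))
    return math.atan2(-s, c)


def fit_gabor(field: np.ndarray, n_restarts: int = 5, early_exit: float = 0.95,
              degenerate_norm: float = 1e-8, seed: int = 0) -> GaborParams:
    """Least-squares 2D Gabor fit to one receptive-field half.

    Returns a flagged degenerate result for near-zero fields.  The amplitude
    is reported positive (phase shifted by pi when the optimiser lands on a
    negative amplitude) and the orientation folded into [0, pi) with the
    carrier frequency kept positive.
    """
    field = np.asarray(field, dtype=float)
    p = field.shape[0]
    power = float(np.sum(field ** 2))
    if power < degenerate_norm ** 2:
        return GaborParams(degenerate=True)

    y, x = np.mgrid[0:p, 0:p].astype(float)
    w = field ** 2
    cx = float(np.sum(x * w) / np.sum(w))
    cy = float(np.sum(y * w) / np.sum(w))
    f0, th0 = _fft_init(field)
    amp0 = float(np.max(np.abs(field)))
    sig0 = max(p / 5.0, 1.0)

    lower = [0.0, -p, -p, 0.4, 0.4, 0.25 / p, th0 - np.pi, -2 * np.pi, -abs(amp0) - 1e-9]
    upper = [3 * amp0 + 1e-9, 2 * p, 2 * p, 2.0 * p, 2.0 * p, 0.75, th0 + np.pi,
             2 * np.pi, abs(amp0) + 1e-9]

    def residuals(params):
        return (_gabor_values(params, x, y) - field).ravel()

    rng = np.random.default_rng(seed)
    best = None
    best_sse = np.inf
    for trial in range(max(1, n_restarts)):
        if trial == 0:
            f_t, th_t, cx_t, cy_t, sig_t = f0, th0, cx, cy, sig0
        else:
            f_t = float(np.clip(f0 * rng.uniform(0.6, 1.6), 0.3 / p, 0.7))
            th_t = th0 + rng.uniform(-0.6, 0.6)
            cx_t = cx + rng.uniform(-p / 6, p / 6)
            cy_t = cy + rng.uniform(-p / 6, p / 6)
            sig_t = sig0 * rng.uniform(0.5, 1.5)
        ph_t = _phase_init(field, f_t, th_t, x, y, cx_t, cy_t)
        x0_vec = np.array([amp0, cx_t, cy_t, sig_t, sig_t, f_t, th_t, ph_t, 0.0])
        x0_vec = np.clip(x0_vec, lower, upper)
        try:
            sol = least_squares(residuals, x0_vec, bounds=(lower, upper),
                                max_nfev=300, method="trf")
        except Exception:
            continue
        sse = float(np.sum(sol.fun ** 2))
        if sse < best_sse:
            best_sse = sse
            best = sol.x.copy()
        if 1.0 - best_sse / power >= early_exit:
            break

    if best is None:
        return GaborParams(degenerate=True)

    amp, x0, y0, s_par, s_orth, freq, theta, phase, offset = best
    if amp < 0:
        amp = -amp
        phase = phase + np.pi
    if freq < 0:
        freq = -freq
        theta = theta + np.pi
        phase = -phase
    # fold orientation into [0, pi); a pi rotation flips the carrier direction,
    # equivalent to negating frequency, compensated by negating the phase.
    theta = theta % (2 * np.pi)
    if theta >= np.pi:
        theta -= np.pi
        phase = -phase
    phase = (phase + np.pi) % (2 * np.pi) - np.pi
    goodness = max(0.0, 1.0 - best_sse / power)
    return GaborParams(amplitude=float(amp), x0=float(x0), y0=float(y0),
                       sigma_par=float(s_par), sigma_orth=float(s_orth),
                       frequency=float(freq), orientation=float(theta),
                       phase=float(phase), offset=float(offset),
                       goodness=float(goodness))


def circular_mean_orientation(orientations: np.ndarray) -> float:
    """Mean of axial data (mod pi) via doubled-angle vector averaging."""
    orientations = np.asarray(orientations, dtype=float)
    z = np.exp(2j * orientations).mean()
    if abs(z) < 1e-12:
        return 0.0
    return float((np.angle(z) / 2.0) % np.pi)


def model_probe_params(
    fits: list[GaborParams],
    half_norms: list[float] | None = None,
    monocular_frac: float = 0.1,
) -> ProbeParams | None:
    """Combine per-half Gabor fits into one probe setting for a model.

    Halves with a fit flagged degenerate are skipped.  If ``half_norms`` is
    given (same order as ``fits``, grouped per subunit in consecutive pairs),
    a half whose norm is below ``monocular_frac`` of its subunit's dominant
    half is treated as monocular and excluded from the means.  Returns None
    when no half survives.
    """
    keep = [not f.degenerate and f.frequency > 0 for f in fits]
    if half_norms is not None:
        norms = np.asarray(half_norms, dtype=float)
        for start in range(0, len(fits), 2):
            pair = norms[start : start + 2]
            dominant = pair.max() if len(pair) else 0.0
            for off in range(len(pair)):
                if pair[off] < monocular_frac * dominant:
                    keep[start + off] = False
    kept = [f for f, k in zip(fits, keep) if k]
    if not kept:
        return None
    freq = float(np.mean([f.frequency for f in kept]))
    theta = circular_mean_orientation(np.array([f.orientation for f in kept]))
    return ProbeParams(frequency=freq, orientation=theta)
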