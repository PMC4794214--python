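"""Sine-grating and bar stimuli, and 2D binocular response maps.

A response map varies a stimulus parameter (grating phase, or bar shift)
independently in the two eyes and records the model response for every
combination.  Constant-disparity stimuli lie on diagonals; zero disparity on
the main diagonal.

Every stimulus pair is passed through the same per-eye centring and
normalisation as the training patches before filtering.  Because that
preprocessing acts per eye and then rescales the concatenated vector by a
factor that depends only on which eyes carry non-zero content, maps can be
evaluated from per-eye response banks instead of materialising every
binocular pair; the two paths agree exactly and the equivalence is tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cells import ComplexCellModel
from .gabor import ProbeParams
from .patches import preprocess_vector, _EYE_NORM_EPS

__all__ = [
    "ResponseMap",
    "make_grating",
    "make_bar",
    "phase_phase_map",
    "bar_shift_map",
    "binocular_response_map",
]


@dataclass
class ResponseMap:
    """values[i, j] = response at left parameter axis[i], right parameter axis[j]."""

    values: np.ndarray
    left_axis: np.ndarray
    right_axis: np.ndarray
    stimulus_kind: str  # grating | bar
    model_id: str | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("response map contains non-finite values")
        if (np.diff(self.left_axis) <= 0).any() or (np.diff(self.right_axis) <= 0).any():
            raise ValueError("axes must be strictly increasing")


def make_grating(
    patch_px: int,
    frequency: float,
    orientation: float,
    phase: float,
    amplitude: float = 1.0,
) -> np.ndarray:
    """sin-phase grating sampled at pixel centres.

    g(x, y) = amplitude * sin(2 pi f (x cos(theta) + y sin(theta)) + phase),
    with x the column and y the row index.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    y, x = np.mgrid[0:patch_px, 0:patch_px].astype(float)
    u = x * np.cos(orientation) + y * np.sin(orientation)
    return amplitude * np.sin(2 * np.pi * frequency * u + phase)


def make_bar(
    patch_px: int,
    bar_width: float,
    orientation: float,
    shift: float,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Bright bar on a zero background, anti-aliased across its edges.

    The bar spans the whole patch along its orientation ("infinite" height)
    and has the given width across it; ``shift`` displaces the bar from the
    patch centre along the across-bar axis u = x cos(theta) + y sin(theta),
    in pixels (half-pixel shifts are supported through area sampling of the
    edge pixels).
    """
    if bar_width <= 0:
        raise ValueError("bar_width must be positive")
    p = patch_px
    c = (p - 1) / 2.0
    y, x = np.mgrid[0:p, 0:p].astype(float)
    u = (x - c) * np.cos(orientation) + (y - c) * np.sin(orientation)
    lo = shift - bar_width / 2.0
    hi = shift + bar_width / 2.0
    coverage = np.clip(np.minimum(u + 0.5, hi) - np.maximum(u - 0.5, lo), 0.0, 1.0)
    return amplitude * coverage


def _preprocess_bank(bank: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre and unit-normalise each monocular stimulus; flag blank ones."""
    flat = bank.reshape(bank.shape[0], -1).astype(float)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    alive = norms > _EYE_NORM_EPS
    flat[alive] /= norms[alive, None]
    flat[~alive] = 0.0
    return flat, alive


def binocular_response_map(
    model: ComplexCellModel,
    left_bank: np.ndarray,
    right_bank: np.ndarray,
    left_axis: np.ndarray,
    right_axis: np.ndarray,
    stimulus_kind: str,
    model_id=None,
) -> ResponseMap:
    """Model responses over all (left stimulus, right stimulus) combinations.

    Each binocular pair is implicitly preprocessed (per-eye centring and
    normalisation, then whole-vector renormalisation) before filtering; the
    computation is factorised through per-eye subunit response banks.
    """
    half = model.patch_px ** 2
    filters = model.subunit_filters
    fl, fr = filters[:, :half], filters[:, half:]
    sl, alive_l = _preprocess_bank(np.asarray(left_bank))
    sr, alive_r = _preprocess_bank(np.asarray(right_bank))
    rl = fl @ sl.T  # n_subunits x S_left
    rr = fr @ sr.T  # n_subunits x S_right
    # Whole-vector renormalisation: concatenated norm is sqrt(#alive halves).
    n_alive = alive_l[:, None].astype(float) + alive_r[None, :].astype(float)
    scale = np.zeros_like(n_alive)
    nz = n_alive > 0
    scale[nz] = 1.0 / np.sqrt(n_alive[nz])
    lin = rl[:, :, None] + rr[:, None, :]  # n_subunits x S_left x S_right
    lin = lin * scale[None, :, :]
    if model.rule == "energy":
        values = np.sum(lin ** 2, axis=0)
    else:
        values = np.max(np.abs(lin), axis=0)
    return ResponseMap(values=values, left_axis=np.asarray(left_axis, dtype=float),
                       right_axis=np.asarray(right_axis, dtype=float),
                       stimulus_kind=stimulus_kind, model_id=model_id)


def phase_phase_map(
    model: ComplexCellModel,
    probe: ProbeParams,
    n_steps: int = 100,
    amplitude: float = 1.0,
    model_id=None,
) -> ResponseMap:
    """Response over an n_steps x n_steps grid of left/right grating phases.

    Phases cover [-pi, pi) without the duplicate endpoint; zero-disparity
    stimulus pairs lie on the main diagonal.
    """
    phases = -np.pi + 2 * np.pi * np.arange(n_steps) / n_steps
    bank = np.stack([
        make_grating(model.patch_px, probe.frequency, probe.orientation, ph, amplitude)
        for ph in phases
    ])
    return binocular_response_map(model, bank, bank, phases, phases,
                                  "grating", model_id)


def bar_shift_map(
    model: ComplexCellModel,
    probe: ProbeParams,
    shift_min: float = -12.5,
    shift_max: float = 12.5,
    n_steps: int = 51,
    amplitude: float = 1.0,
    model_id=None,
) -> ResponseMap:
    """Response over a grid of left/right bar shifts.

    The bar width is half the probe wavelength and its orientation matches
    the probe orientation; shifts are measured orthogonal to the bar.
    """
    shifts = np.linspace(shift_min, shift_max, n_steps)
    width = probe.wavelength / 2.0
    bank = np.stack([
        make_bar(model.patch_px, width, probe.orientation, s, amplitude)
        for s in shifts
    ])
    return binocular_response_map(model, bank, bank, shifts, shifts, "bar", model_id)


def refine_probe_by_response(
    model: ComplexCellModel,
    probe0: ProbeParams,
    freq_span: float = 1.6,
    n_freq: int = 7,
    orient_span: float = np.pi / 3,
    n_orient: int = 9,
    n_steps: int = 24,
) -> ProbeParams:
    """Pick the probe grating that maximises the model's peak map response.

    Searches a coarse grid around an initial estimate (typically the mean
    fitted Gabor parameters): frequencies geometrically spaced within
    ``freq_span`` of the seed, orientations within +-``orient_span``.  The
    selection criterion is the maximum cell of a low-resolution phase-phase
    map, so the probe aligns with whatever stimulus drives the model
    hardest.
    """
    best = probe0
    best_resp = -np.inf
    freqs = probe0.frequency * np.geomspace(1.0 / freq_span, freq_span, n_freq)
    orients = probe0.orientation + np.linspace(-orient_span, orient_span, n_orient)
    for f in freqs:
        if not 0.02 <= f <= 0.5:
            continue
        for theta in orients:
            cand = ProbeParams(frequency=float(f), orientation=float(theta % np.pi))
            resp = float(phase_phase_map(model, cand, n_steps).values.max())
            if resp > best_resp:
                best_resp = resp
                best = cand
    return best


def binocular_stimulus_vector(left: np.ndarray, right: np.ndarray, patch_px: int) -> np.ndarray:
    """Concatenate and preprocess one explicit binocular stimulus pair."""
    vec = np.concatenate([np.asarray(left, dtype=float).ravel(),
                          np.asarray(right, dtype=float).ravel()])
    return preprocess_vector(vec, patch_px)
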