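"""Synthetic binocular imagery and ground-truth subspace patch sets.

Two generators live here.  :func:`generate_stereo_pair` emulates calibrated
luminance stereo photographs: a naturalistic (power-law amplitude spectrum)
base image, a smooth horizontal disparity field concentrated near zero, and a
small amount of independent sensor noise per eye.  Vertical disparity is fixed
at zero, matching a rig in which elevation and cyclovergence differences
between the eyes vanish.

:func:`generate_isa_ground_truth_patches` draws patches from the exact
generative model that independent subspace analysis assumes — orthonormal
components grouped into subspaces, sources isotropic within a subspace with a
heavy-tailed radial distribution — so subspace recovery can be benchmarked
against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .patches import PatchMatrix

__all__ = [
    "StereoImagePair",
    "DisparityFieldSpec",
    "generate_disparity_field",
    "generate_stereo_pair",
    "generate_isa_ground_truth_patches",
    "save_stereo_pair",
    "load_stereo_pair",
]


@dataclass
class StereoImagePair:
    """Left/right luminance rasters plus angular calibration metadata.

    ``pixel_scale`` is arc minutes of visual angle per pixel; it is carried as
    metadata only and never enters the computations.
    """

    left: np.ndarray
    right: np.ndarray
    pixel_scale: float = 1.0

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError(
                f"left/right shapes differ: {self.left.shape} vs {self.right.shape}"
            )
        if not (np.isfinite(self.left).all() and np.isfinite(self.right).all()):
            raise ValueError("stereo pair contains non-finite values")


@dataclass
class DisparityFieldSpec:
    """Horizontal disparity field: constant offset or a smooth random field.

    ``amplitude`` is in pixels: the constant value in ``constant`` mode, the
    standard deviation of the zero-mean field in ``smooth-random`` mode.
    ``correlation_length`` is the Gaussian smoothing length in pixels.
    """

    mode: str = "smooth-random"
    amplitude: float = 1.0
    correlation_length: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "smooth-random"):
            raise ValueError(f"unknown disparity field mode {self.mode!r}")
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise ValueError("amplitude must be finite and >= 0")
        if not np.isfinite(self.correlation_length) or self.correlation_length <= 0:
            raise ValueError("correlation_length must be finite and > 0")


def generate_disparity_field(width: int, height: int, spec: DisparityFieldSpec) -> np.ndarray:
    """Realize the horizontal disparity field on a (height, width) grid."""
    if spec.mode == "constant":
        return np.full((height, width), float(spec.amplitude))
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((height, width))
    smooth = ndimage.gaussian_filter(noise, sigma=spec.correlation_length, mode="reflect")
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros((height, width))
    return smooth * (spec.amplitude / sd)


def _power_law_noise(shape: tuple[int, int], slope: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise shaped so its amplitude spectrum is proportional to f**slope."""
    h, w = shape
    spectrum = np.fft.fft2(rng.standard_normal(shape))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    gain = np.zeros_like(f)
    nonzero = f > 0
    gain[nonzero] = f[nonzero] ** slope
    img = np.fft.ifft2(spectrum * gain).real
    return img


def generate_stereo_pair(
    width: int,
    height: int,
    field: DisparityFieldSpec,
    spectral_slope: float = -1.0,
    seed: int = 0,
    noise_sigma_frac: float = 0.01,
    mean_level: float = 0.5,
    contrast: float = 0.1,
    pixel_scale: float = 1.0,
) -> StereoImagePair:
    """Generate one synthetic calibrated stereo pair.

    The left eye sees power-law filtered noise rescaled to the requested mean
    luminance and RMS contrast.  The right eye sees the same scene warped
    horizontally by the disparity field (cubic interpolation); positive
    disparity d means right(x, y) = left(x + d, y).  Both eyes then receive
    independent additive Gaussian sensor noise with standard deviation
    ``noise_sigma_frac`` times the image RMS contrast.  Columns inside the
    warp margin are cropped so no edge artefact survives into patch sampling;
    the returned images have exactly the requested size.
    """
    for name, val in [("width", width), ("height", height), ("spectral_slope", spectral_slope),
                      ("noise_sigma_frac", noise_sigma_frac), ("mean_level", mean_level),
                      ("contrast", contrast)]:
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val!r}")
    if width < 64 or height < 64:
        raise ValueError("width and height must be at least 64 px")
    if noise_sigma_frac < 0:
        raise ValueError("noise_sigma_frac must be >= 0")

    margin = int(math.ceil(field.amplitude)) + 2
    wide = width + 2 * margin
    rng = np.random.default_rng(seed)

    base = _power_law_noise((height, wide), spectral_slope, rng)
    base = base - base.mean()
    sd = base.std()
    if sd > 0:
        base = base * (contrast / sd)
    base = base + mean_level

    disp = generate_disparity_field(wide, height, field)
    rows, cols = np.mgrid[0:height, 0:wide].astype(float)
    right_wide = ndimage.map_coordinates(base, [rows, cols + disp], order=3, mode="reflect")

    left = base[:, margin:wide - margin].copy()
    right = right_wide[:, margin:wide - margin].copy()

    if noise_sigma_frac > 0:
        sigma = noise_sigma_frac * contrast
        left = left + sigma * rng.standard_normal(left.shape)
        right = right + sigma * rng.standard_normal(right.shape)

    return StereoImagePair(left=left, right=right, pixel_scale=pixel_scale)


def generate_isa_ground_truth_patches(
    n_patches: int,
    patch_px: int,
    n_subspaces: int,
    subunits_per_subspace: int,
    seed: int = 0,
) -> tuple[PatchMatrix, np.ndarray]:
    """Draw binocular patch vectors from the subspace generative model.

    Components ``W`` are J orthonormal rows in the M = 2*patch_px**2 pixel
    space (J = n_subspaces * subunits_per_subspace).  For each patch, every
    subspace contributes a source vector r*u with u uniform on the unit sphere
    of the subspace and radius r drawn from an exponential distribution, so
    sources are isotropic within a subspace and their norms are sparse
    (heavy-tailed) across patches.  Patches are ``X = A @ W``.

    Returns the patch matrix (stage "raw") and the true component matrix
    ``W`` (J x M); rows j belong to subspace j // subunits_per_subspace.
    """
    if n_patches <= 0:
        raise ValueError("n_patches must be positive")
    m = 2 * patch_px * patch_px
    j = n_subspaces * subunits_per_subspace
    if j > m:
        raise ValueError(
            f"infeasible dimensions: {n_subspaces}x{subunits_per_subspace} components "
            f"exceed patch dimension {m}"
        )
    rng = np.random.default_rng(seed)
    # Orthonormal rows via QR of an M x J Gaussian matrix.
    q, _ = np.linalg.qr(rng.standard_normal((m, j)))
    components = q.T  # J x M

    d = subunits_per_subspace
    directions = rng.standard_normal((n_patches, n_subspaces, d))
    directions /= np.linalg.norm(directions, axis=2, keepdims=True)
    radii = rng.exponential(scale=1.0, size=(n_patches, n_subspaces, 1))
    sources = (directions * radii).reshape(n_patches, j)

    data = sources @ components
    return PatchMatrix(data=data, patch_px=patch_px, stage="raw"), components


# ---------------------------------------------------------------------------
# On-disk format: 16-bit grayscale PNG per eye plus a key-value sidecar.

def _to_uint16(img: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo if hi > lo else 1.0
    scaled = np.clip((img - lo) / span, 0.0, 1.0)
    return np.round(scaled * 65535).astype(np.uint16)


def save_stereo_pair(pair: StereoImagePair, directory: str | Path, stem: str) -> None:
    """Write ``<stem>_L.png``, ``<stem>_R.png`` and ``<stem>.meta.txt``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lo = float(min(pair.left.min(), pair.right.min()))
    hi = float(max(pair.left.max(), pair.right.max()))
    iio.imwrite(directory / f"{stem}_L.png", _to_uint16(pair.left, lo, hi))
    iio.imwrite(directory / f"{stem}_R.png", _to_uint16(pair.right, lo, hi))
    meta = {
        "pixel_scale_arcmin_per_px": pair.pixel_scale,
        "value_min": lo,
        "value_max": hi,
    }
    with open(directory / f"{stem}.meta.txt", "w") as fh:
        for key, val in meta.items():
            fh.write(f"{key} = {val!r}\n")


def load_stereo_pair(directory: str | Path, stem: str) -> StereoImagePair:
    directory = Path(directory)
    meta: dict[str, float] = {}
    with open(directory / f"{stem}.meta.txt") as fh:
        for line in fh:
            if "=" in line:
                key, val = line.split("=", 1)
                meta[key.strip()] = float(eval(val.strip(), {"__builtins__": {}}))
    lo, hi = meta["value_min"], meta["value_max"]
    span = hi - lo if hi > lo else 1.0

    def read(path: Path) -> np.ndarray:
        raw = iio.imread(path).astype(float)
        return raw / 65535.0 * span + lo

    left = read(directory / f"{stem}_L.png")
    right = read(directory / f"{stem}_R.png")
    if left.shape != right.shape:
        raise ValueError(f"stereo pair {stem!r}: left/right image shapes differ")
    return StereoImagePair(left=left, right=right,
                           pixel_scale=meta.get("pixel_scale_arcmin_per_px", 1.0))
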