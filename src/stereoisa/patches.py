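"""Binocular patch sampling, per-eye normalization and PCA whitening.

A binocular patch is the concatenation of a left-eye and a right-eye p x p
patch cut at the same image coordinates, vectorised row-major, left eye first
(the on-disk contract for every array in this package).

Preprocessing removes luminance and contrast information per eye: each eye's
half is centred on its own mean and scaled to unit norm, then the whole
2*p**2 vector is renormalised to unit length, which leaves each half with
norm 1/sqrt(2).  Rows whose per-eye norm underflows (e.g. a constant patch)
carry no structure and are dropped.

Whitening is plain PCA: centred data are projected onto the top-k
eigenvectors of the sample covariance and rescaled to unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatchMatrix",
    "WhiteningTransform",
    "sample_patches",
    "preprocess_patches",
    "preprocess_vector",
    "fit_whitening",
    "apply_whitening",
    "filters_to_pixel_space",
]

_EYE_NORM_EPS = 1e-10


@dataclass
class PatchMatrix:
    """N x M matrix of vectorised binocular patches (M = 2 * patch_px**2)."""

    data: np.ndarray
    patch_px: int
    stage: str = "raw"  # raw | preprocessed | whitened
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("patch matrix must be 2-D")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.data.shape[1]


@dataclass
class WhiteningTransform:
    """PCA whitening: z = forward @ (x - mean); x ~= mean + inverse @ z."""

    mean: np.ndarray
    forward: np.ndarray      # K x M
    inverse: np.ndarray      # M x K
    eigenvalues: np.ndarray  # length K, descending

    @property
    def k(self) -> int:
        return self.forward.shape[0]


def sample_patches(pairs, n: int, patch_px: int, seed: int = 0) -> PatchMatrix:
    """Cut ``n`` binocular patches at uniform random positions.

    Positions are 0-based with a top-left origin; the same coordinates are
    used in both eyes (corresponding retinal locations).  Patches are drawn
    uniformly over (pair, row, column) triples with valid extents.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no stereo pairs given")
    for idx, pair in enumerate(pairs):
        h, w = pair.left.shape
        if h < patch_px or w < patch_px:
            raise ValueError(
                f"pair {idx}: image {h}x{w} smaller than patch size {patch_px}"
            )
    rng = np.random.default_rng(seed)
    p = patch_px
    m = 2 * p * p
    out = np.empty((n, m))
    pair_idx = rng.integers(0, len(pairs), size=n)
    for i in range(n):
        pair = pairs[pair_idx[i]]
        h, w = pair.left.shape
        r = rng.integers(0, h - p + 1)
        c = rng.integers(0, w - p + 1)
        out[i, : p * p] = pair.left[r : r + p, c : c + p].ravel()
        out[i, p * p :] = pair.right[r : r + p, c : c + p].ravel()
    return PatchMatrix(data=out, patch_px=patch_px, stage="raw")


def _normalize_halves(data: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray]:
    """Centre and unit-normalise each half in place; flag degenerate rows."""
    ok = np.ones(data.shape[0], dtype=bool)
    for sl in (slice(0, half), slice(half, None)):
        block = data[:, sl]
        block -= block.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(block, axis=1)
        ok &= norms > _EYE_NORM_EPS
        safe = np.where(norms > _EYE_NORM_EPS, norms, 1.0)
        block /= safe[:, None]
    return data, ok


def preprocess_patches(raw: PatchMatrix) -> PatchMatrix:
    """Per-eye centring and normalisation, then whole-vector renormalisation.

    Degenerate rows (per-eye norm underflow) are dropped; their count is
    recorded on the returned matrix as ``n_dropped``.
    """
    if raw.stage != "raw":
        raise ValueError(f"expected stage 'raw', got {raw.stage!r}")
    half = raw.patch_px ** 2
    data, ok = _normalize_halves(raw.data.copy(), half)
    data = data[ok]
    # Both halves are unit vectors here, so the full norm is sqrt(2) exactly.
    data /= np.linalg.norm(data, axis=1, keepdims=True)
    return PatchMatrix(
        data=data,
        patch_px=raw.patch_px,
        stage="preprocessed",
        n_dropped=int((~ok).sum()),
    )


def preprocess_vector(x: np.ndarray, patch_px: int) -> np.ndarray:
    """Preprocess a single binocular stimulus vector, degenerate-safe.

    Same transform as :func:`preprocess_patches`, but a half whose centred
    norm underflows (e.g. a blank eye) is left at zero rather than dropped,
    and the final renormalisation uses the norm of the surviving content.  An
    entirely blank stimulus maps to the zero vector.
    """
    x = np.asarray(x, dtype=float).copy()
    half = patch_px ** 2
    if x.shape != (2 * half,):
        raise ValueError(f"stimulus length {x.shape} != {(2 * half,)}")
    for sl in (slice(0, half), slice(half, None)):
        block = x[sl] - x[sl].mean()
        norm = np.linalg.norm(block)
        x[sl] = block / norm if norm > _EYE_NORM_EPS else 0.0
    total = np.linalg.norm(x)
    return x / total if total > _EYE_NORM_EPS else x * 0.0


def fit_whitening(x: PatchMatrix, k: int) -> WhiteningTransform:
    """Fit PCA whitening with ``k`` retained dimensions.

    The data mean is subtracted before the eigendecomposition.  Requesting
    more dimensions than the sample covariance's numerical rank is an error.
    """
    n, m = x.data.shape
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    if n <= k:
        raise ValueError(f"need more samples than retained dimensions (N={n}, k={k})")
    mean = x.data.mean(axis=0)
    centred = x.data - mean
    cov = centred.T @ centred / n
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    rank = int(np.sum(eigvals > max(eigvals[0], 0.0) * 1e-10))
    if k > rank:
        raise ValueError(
            f"requested k={k} exceeds numerical rank {rank} of the sample covariance"
        )
    vals = eigvals[:k]
    vecs = eigvecs[:, :k]
    forward = (vecs / np.sqrt(vals)).T       # K x M
    inverse = vecs * np.sqrt(vals)           # M x K
    return WhiteningTransform(mean=mean, forward=forward, inverse=inverse,
                              eigenvalues=vals)


def apply_whitening(t: WhiteningTransform, x: PatchMatrix) -> PatchMatrix:
    if x.m != t.forward.shape[1]:
        raise ValueError(
            f"dimension mismatch: data has {x.m} columns, transform expects "
            f"{t.forward.shape[1]}"
        )
    z = (x.data - t.mean) @ t.forward.T
    return PatchMatrix(data=z, patch_px=x.patch_px, stage="whitened",
                       n_dropped=x.n_dropped)


def filters_to_pixel_space(t: WhiteningTransform, w: np.ndarray) -> np.ndarray:
    """Map whitened-space analysis filters to pixel-space analysis filters.

    For each row ``w_j`` the returned row ``v_j = forward.T @ w_j`` satisfies
    ``v_j @ patch == w_j @ (forward @ patch)`` exactly, so model responses can
    be evaluated directly on preprocessed pixel stimuli.
    """
    w = np.atleast_2d(np.asarray(w, dtype=float))
    if w.shape[1] != t.k:
        raise ValueError(
            f"filter dimension {w.shape[1]} does not match whitened dimension {t.k}"
        )
    return w @ t.forward
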