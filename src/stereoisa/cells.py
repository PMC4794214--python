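"""Complex-cell response rules and the reference binocular energy model.

A complex-cell model is a set of binocular linear subunit filters (pixel
space, left half then right half) combined either by summing squared subunit
responses (the energy rule) or by taking the maximum absolute subunit
response (max pooling).  The classical closed-form binocular energy model
over quadrature Gabor responses, and the phase-difference readout derived
from it, live here as analytic references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ComplexCellModel",
    "complex_response",
    "binocular_energy",
    "phase_difference_from_energies",
    "gabor_patch",
    "make_ideal_detector",
    "make_monocular_detector",
]


@dataclass
class ComplexCellModel:
    """Binocular complex-cell model built from linear subunit filters."""

    subunit_filters: np.ndarray  # n_subunits x M, pixel space, left || right
    rule: str = "energy"         # energy | maxpool
    patch_px: int = 0
    subspace_id: int | None = None
    probe_params: "object | None" = None

    def __post_init__(self) -> None:
        self.subunit_filters = np.atleast_2d(np.asarray(self.subunit_filters, dtype=float))
        if self.subunit_filters.shape[0] < 2:
            raise ValueError("a complex-cell model needs at least 2 subunits")
        if self.rule not in ("energy", "maxpool"):
            raise ValueError(f"unknown combination rule {self.rule!r}")
        if self.patch_px == 0:
            half = self.subunit_filters.shape[1] // 2
            p = int(round(half ** 0.5))
            if 2 * p * p != self.subunit_filters.shape[1]:
                raise ValueError("cannot infer patch size from filter length")
            self.patch_px = p

    @property
    def n_subunits(self) -> int:
        return self.subunit_filters.shape[0]


def complex_response(model: ComplexCellModel, stimulus: np.ndarray) -> float:
    """Response to a preprocessed binocular stimulus vector (always >= 0)."""
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.shape != (model.subunit_filters.shape[1],):
        raise ValueError(
            f"stimulus length {stimulus.shape} does not match filter length "
            f"{model.subunit_filters.shape[1]}"
        )
    lin = model.subunit_filters @ stimulus
    if model.rule == "energy":
        return float(np.sum(lin ** 2))
    return float(np.max(np.abs(lin)))


def binocular_energy(r_l: float, i_l: float, r_r: float, i_r: float) -> float:
    """Energy-model response from even (R) and odd (I) Gabor responses per eye."""
    for v in (r_l, i_l, r_r, i_r):
        if not np.isfinite(v):
            raise ValueError("subunit responses must be finite")
    return (r_l + r_r) ** 2 + (i_l + i_r) ** 2


def phase_difference_from_energies(r_l: float, i_l: float, r_r: float, i_r: float) -> float:
    """cos of the interocular phase difference from quadrature responses.

    cos(dphi) = (bem - RL^2 - IL^2 - RR^2 - IR^2)
                / (2 sqrt((RL^2 + IL^2)(RR^2 + IR^2))),
    clipped to [-1, 1].  Undefined when either eye's monocular energy is zero.
    """
    e_l = r_l ** 2 + i_l ** 2
    e_r = r_r ** 2 + i_r ** 2
    if e_l <= 0 or e_r <= 0:
        raise ValueError("phase difference undefined: zero monocular energy")
    bem = binocular_energy(r_l, i_l, r_r, i_r)
    cos_dphi = (bem - e_l - e_r) / (2.0 * np.sqrt(e_l * e_r))
    return float(np.clip(cos_dphi, -1.0, 1.0))


def gabor_patch(
    patch_px: int,
    frequency: float,
    orientation: float,
    phase: float,
    sigma: float | None = None,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """p x p Gabor: Gaussian envelope times cos(2 pi f u + phase).

    The carrier varies along u = x cos(theta) + y sin(theta); x is the column
    coordinate, y the row coordinate, origin at the patch centre by default.
    """
    p = patch_px
    if sigma is None:
        sigma = p / 5.0
    cx, cy = center if center is not None else ((p - 1) / 2.0, (p - 1) / 2.0)
    y, x = np.mgrid[0:p, 0:p].astype(float)
    u = (x - cx) * np.cos(orientation) + (y - cy) * np.sin(orientation)
    v = -(x - cx) * np.sin(orientation) + (y - cy) * np.cos(orientation)
    envelope = np.exp(-(u ** 2 + v ** 2) / (2.0 * sigma ** 2))
    return envelope * np.cos(2.0 * np.pi * frequency * u + phase)


def make_ideal_detector(
    patch_px: int,
    frequency: float,
    orientation: float = 0.0,
    phase_disparity: float = 0.0,
    rule: str = "energy",
    sigma: float | None = None,
) -> ComplexCellModel:
    """Quadrature Gabor-pair detector tuned to one interocular phase disparity.

    Subunit 1 has left/right Gabors with carrier phases (0, phase_disparity);
    subunit 2 is its quadrature partner (both phases shifted by pi/2).  Under
    the energy rule the response to matched-frequency gratings depends only on
    the interocular phase difference, peaking where it equals
    ``phase_disparity``.
    """
    if frequency <= 0 or 1.0 / frequency < 4.0:
        raise ValueError("carrier wavelength must be at least 4 px")
    subunits = []
    for quad in (0.0, np.pi / 2.0):
        left = gabor_patch(patch_px, frequency, orientation, quad, sigma)
        right = gabor_patch(patch_px, frequency, orientation, quad + phase_disparity, sigma)
        filt = np.concatenate([left.ravel(), right.ravel()])
        subunits.append(filt / np.linalg.norm(filt))
    return ComplexCellModel(subunit_filters=np.array(subunits), rule=rule,
                            patch_px=patch_px)


def make_monocular_detector(
    patch_px: int,
    frequency: float,
    orientation: float = 0.0,
    eye: str = "left",
    rule: str = "energy",
    sigma: float | None = None,
) -> ComplexCellModel:
    """Quadrature pair confined to one eye; the other eye's halves are zero."""
    if eye not in ("left", "right"):
        raise ValueError("eye must be 'left' or 'right'")
    subunits = []
    blank = np.zeros(patch_px * patch_px)
    for quad in (0.0, np.pi / 2.0):
        g = gabor_patch(patch_px, frequency, orientation, quad, sigma).ravel()
        halves = [g, blank] if eye == "left" else [blank, g]
        filt = np.concatenate(halves)
        subunits.append(filt / np.linalg.norm(filt))
    return ComplexCellModel(subunit_filters=np.array(subunits), rule=rule,
                            patch_px=patch_px)
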