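"""Config-driven end-to-end pipeline with per-stage persistence and resume.

Stages: simulate (or ingest an image directory) -> patches (sample,
preprocess, whiten) -> isa -> probe (Gabor fits + phase-phase maps for both
combination rules) -> metrics (characterisation table + population summary).
Each stage writes one artifact into the run directory and is skipped when
that artifact already exists, so deleting a downstream artifact and rerunning
reproduces it bit-identically from the persisted upstream state.  All
randomness derives from the master seed through stable per-stage hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import gabor, isa, metrics, patches, probing, synthetic
from .cells import ComplexCellModel

__all__ = ["RunConfig", "run_pipeline", "derive_seed", "desk_scale_config",
           "load_image_directory", "stage_simulate", "stage_patches",
           "stage_isa", "stage_probe", "stage_metrics"]

log = logging.getLogger("stereoisa")


@dataclass
class RunConfig:
    """Everything a full run needs; defaults are the full-scale study settings."""

    # data source: "synthetic" or a directory of <stem>_L/_R image pairs
    source: str = "synthetic"
    n_pairs: int = 139
    image_size: int = 1201
    disparity_amplitude: float = 2.0
    disparity_correlation_length: float = 40.0
    spectral_slope: float = -1.0
    # patches
    n_patches: int = 500_000
    patch_px: int = 25
    whitening_k: int | None = None  # default: n_subspaces * subunits_per_subspace
    # model
    n_subspaces: int = 200
    subunits_per_subspace: int = 2
    isa_max_iter: int = 500
    isa_tol: float = 1e-7
    # extra ISAOptions overrides (restarts, burn_in, polish budgets, ...)
    isa_options: dict = field(default_factory=dict)
    # probing / metrics
    n_phase_steps: int = 100
    # probe selection: gratings at the mean fitted Gabor parameters, then
    # refined so the model's peak response is maximised ("response_max");
    # "gabor_mean" uses the fitted means directly
    probe_mode: str = "response_max"
    rules: tuple[str, ...] = ("energy", "maxpool")
    ddi_threshold: float = 0.6
    n_boot: int = 200
    # bookkeeping
    seed: int = 0
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        for name in ("n_pairs", "image_size", "n_patches", "patch_px",
                     "n_subspaces", "subunits_per_subspace", "n_phase_steps",
                     "n_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def k(self) -> int:
        return self.whitening_k or self.n_subspaces * self.subunits_per_subspace

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rules"] = list(self.rules)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "rules" in raw:
            raw["rules"] = tuple(raw["rules"])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def desk_scale_config(seed: int = 0, out_dir: str = "results/run_desk") -> RunConfig:
    """Scaled-down study conditions: 20 synthetic 512 px pairs, 50k patches,
    50 subspaces."""
    return RunConfig(
        n_pairs=20, image_size=512, n_patches=50_000, n_subspaces=50,
        seed=seed, out_dir=out_dir,
        # lighter multi-start/polish budget for the 100-dimensional fit; the
        # population statistics are insensitive to the residual local optima
        isa_options={"n_restarts": 2, "burn_in": 100, "polish_rounds": 8,
                     "polish_max_iter": 150, "resplit_rounds": 1,
                     "resplit_pairs_per_subspace": 1.0},
    )


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _provenance(cfg: RunConfig, stage: str) -> str:
    return json.dumps({"config": cfg.to_dict(), "stage": stage,
                       "config_hash": cfg.config_hash()}, sort_keys=True)


def load_image_directory(path: str | Path) -> list[synthetic.StereoImagePair]:
    """Ingest <stem>_L.png / <stem>_R.png pairs (PNG or TIFF)."""
    path = Path(path)
    stems = sorted(
        p.name[: -len("_L" + p.suffix)]
        for p in path.iterdir()
        if p.stem.endswith("_L") and p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not stems:
        raise ValueError(f"no *_L/*_R image pairs found in {path}")
    import imageio.v3 as iio

    pairs = []
    for stem in stems:
        if (path / f"{stem}.meta.txt").exists():
            pairs.append(synthetic.load_stereo_pair(path, stem))
            continue
        left = right = None
        for suffix in (".png", ".tif", ".tiff"):
            if (path / f"{stem}_L{suffix}").exists():
                left = iio.imread(path / f"{stem}_L{suffix}").astype(float)
                right_path = path / f"{stem}_R{suffix}"
                if not right_path.exists():
                    raise ValueError(f"pair {stem!r}: missing right image {right_path.name}")
                right = iio.imread(right_path).astype(float)
                break
        if left is None:
            raise ValueError(f"pair {stem!r}: missing left image")
        if left.shape != right.shape:
            raise ValueError(
                f"pair {stem!r}: left shape {left.shape} != right shape {right.shape}"
            )
        pairs.append(synthetic.StereoImagePair(left=left, right=right))
    return pairs


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, run_dir: Path) -> Path:
    """Generate (or locate) the stereo image set."""
    if cfg.source != "synthetic":
        return Path(cfg.source)
    img_dir = run_dir / "images"
    done = img_dir / ".complete"
    if done.exists():
        log.info("simulate: reusing %s", img_dir)
        return img_dir
    seed = derive_seed(cfg.seed, "simulate")
    log.info("simulate: %d pairs of %d px (seed %d)", cfg.n_pairs, cfg.image_size, seed)
    for i in range(cfg.n_pairs):
        fspec = synthetic.DisparityFieldSpec(
            mode="smooth-random",
            amplitude=cfg.disparity_amplitude,
            correlation_length=cfg.disparity_correlation_length,
            seed=derive_seed(seed, f"field{i}"),
        )
        pair = synthetic.generate_stereo_pair(
            cfg.image_size, cfg.image_size, fspec,
            spectral_slope=cfg.spectral_slope,
            seed=derive_seed(seed, f"pair{i}"),
        )
        synthetic.save_stereo_pair(pair, img_dir, f"scene{i:03d}")
    done.touch()
    return img_dir


def stage_patches(cfg: RunConfig, run_dir: Path, img_dir: Path) -> Path:
    """Sample, preprocess and whiten the binocular patch set."""
    out = run_dir / "patches.h5"
    if out.exists():
        log.info("patches: reusing %s", out)
        return out
    pairs = load_image_directory(img_dir)
    seed = derive_seed(cfg.seed, "patches")
    log.info("patches: sampling %d x %d px from %d pairs (seed %d)",
             cfg.n_patches, cfg.patch_px, len(pairs), seed)
    raw = patches.sample_patches(pairs, cfg.n_patches, cfg.patch_px, seed=seed)
    pre = patches.preprocess_patches(raw)
    log.info("patches: %d kept, %d degenerate rows dropped", pre.n, pre.n_dropped)
    transform = patches.fit_whitening(pre, cfg.k)
    white = patches.apply_whitening(transform, pre)
    with h5py.File(out, "w") as fh:
        fh.create_dataset("whitened", data=white.data)
        fh.create_dataset("mean", data=transform.mean)
        fh.create_dataset("forward", data=transform.forward)
        fh.create_dataset("inverse", data=transform.inverse)
        fh.create_dataset("eigenvalues", data=transform.eigenvalues)
        fh.attrs["n_dropped"] = pre.n_dropped
        fh.attrs["patch_px"] = cfg.patch_px
        fh.attrs["provenance"] = _provenance(cfg, "patches")
    return out


def _load_whitening(fh) -> patches.WhiteningTransform:
    return patches.WhiteningTransform(
        mean=fh["mean"][:], forward=fh["forward"][:],
        inverse=fh["inverse"][:], eigenvalues=fh["eigenvalues"][:],
    )


def stage_isa(cfg: RunConfig, run_dir: Path, patches_file: Path) -> Path:
    """Fit the subspace model on the whitened patches."""
    out = run_dir / "isa.h5"
    if out.exists():
        log.info("isa: reusing %s", out)
        return out
    with h5py.File(patches_file, "r") as fh:
        z = fh["whitened"][:]
    opts = isa.ISAOptions(max_iter=cfg.isa_max_iter, tol=cfg.isa_tol,
                          seed=derive_seed(cfg.seed, "isa"), **cfg.isa_options)
    log.info("isa: fitting %d subspaces x %d subunits on %s patches",
             cfg.n_subspaces, cfg.subunits_per_subspace, z.shape[0])
    model = isa.fit_isa(z, cfg.n_subspaces, cfg.subunits_per_subspace, opts)
    log.info("isa: %d iterations, objective %.6f, converged=%s",
             len(model.objective_trace) - 1, model.objective_trace[-1],
             model.converged)
    with h5py.File(out, "w") as fh:
        fh.create_dataset("W", data=model.W)
        fh.create_dataset("objective_trace", data=model.objective_trace)
        fh.attrs["n_subspaces"] = cfg.n_subspaces
        fh.attrs["subunits_per_subspace"] = cfg.subunits_per_subspace
        fh.attrs["converged"] = model.converged
        fh.attrs["provenance"] = _provenance(cfg, "isa")
    return out


def _pixel_filters(patches_file: Path, isa_file: Path):
    with h5py.File(patches_file, "r") as fh:
        transform = _load_whitening(fh)
        patch_px = int(fh.attrs["patch_px"])
    with h5py.File(isa_file, "r") as fh:
        w = fh["W"][:]
        d = int(fh.attrs["subunits_per_subspace"])
    return patches.filters_to_pixel_space(transform, w), d, patch_px


def stage_probe(cfg: RunConfig, run_dir: Path, patches_file: Path, isa_file: Path) -> Path:
    """Gabor-fit every subunit half and compute phase-phase maps per rule."""
    out = run_dir / "probe.h5"
    if out.exists():
        log.info("probe: reusing %s", out)
        return out
    filters, d, patch_px = _pixel_filters(patches_file, isa_file)
    half = patch_px ** 2
    n_models = filters.shape[0] // d

    rows = []
    probes: list[gabor.ProbeParams | None] = []
    for s in range(n_models):
        fits: list[gabor.GaborParams] = []
        norms: list[float] = []
        for j in range(d):
            filt = filters[s * d + j]
            for eye, sl in (("L", slice(0, half)), ("R", slice(half, None))):
                fld = filt[sl].reshape(patch_px, patch_px)
                fit = gabor.fit_gabor(fld, seed=derive_seed(cfg.seed, f"gabor{s}_{j}{eye}"))
                fits.append(fit)
                norms.append(float(np.linalg.norm(fld)))
                rows.append({
                    "model_id": s, "subunit": j, "eye": eye,
                    "half_norm": norms[-1], **dataclasses.asdict(fit),
                })
        probes.append(gabor.model_probe_params(fits, norms))
    if cfg.probe_mode == "response_max":
        for s, probe in enumerate(probes):
            if probe is None:
                continue
            model = ComplexCellModel(subunit_filters=filters[s * d : (s + 1) * d],
                                     rule="energy", patch_px=patch_px)
            probes[s] = probing.refine_probe_by_response(model, probe)
    elif cfg.probe_mode != "gabor_mean":
        raise ValueError(f"unknown probe_mode {cfg.probe_mode!r}")
    n_excluded = sum(p is None for p in probes)
    log.info("probe: %d models, %d excluded (no usable Gabor fit)",
             n_models, n_excluded)
    pd.DataFrame(rows).to_csv(run_dir / "gabor_fits.csv", index=False)

    with h5py.File(out, "w") as fh:
        fh.attrs["patch_px"] = patch_px
        fh.attrs["n_phase_steps"] = cfg.n_phase_steps
        fh.attrs["provenance"] = _provenance(cfg, "probe")
        for s in range(n_models):
            grp = fh.create_group(f"model{s:04d}")
            probe = probes[s]
            grp.attrs["probed"] = probe is not None
            if probe is None:
                continue
            grp.attrs["frequency"] = probe.frequency
            grp.attrs["orientation"] = probe.orientation
            model_filters = filters[s * d : (s + 1) * d]
            for rule in cfg.rules:
                model = ComplexCellModel(subunit_filters=model_filters, rule=rule,
                                         patch_px=patch_px, subspace_id=s)
                rmap = probing.phase_phase_map(model, probe, cfg.n_phase_steps,
                                               model_id=s)
                grp.create_dataset(rule, data=rmap.values)
    return out


def stage_metrics(cfg: RunConfig, run_dir: Path, probe_file: Path) -> Path:
    """Characterise every model and summarise the population per rule."""
    out = run_dir / "summary.json"
    if out.exists():
        log.info("metrics: reusing %s", out)
        return out
    chars_rows = []
    per_rule: dict[str, list[metrics.DisparityCharacterization]] = {
        rule: [] for rule in cfg.rules
    }
    with h5py.File(probe_file, "r") as fh:
        n_steps = int(fh.attrs["n_phase_steps"])
        phase_axis = -np.pi + 2 * np.pi * np.arange(n_steps) / n_steps
        for name in sorted(fh.keys()):
            grp = fh[name]
            if not grp.attrs["probed"]:
                continue
            probe = gabor.ProbeParams(frequency=float(grp.attrs["frequency"]),
                                      orientation=float(grp.attrs["orientation"]))
            for rule in cfg.rules:
                rmap = probing.ResponseMap(values=grp[rule][:], left_axis=phase_axis,
                                           right_axis=phase_axis,
                                           stimulus_kind="grating",
                                           model_id=int(name[5:]))
                char = metrics.characterize_map(rmap, rule, cfg.ddi_threshold, probe)
                per_rule[rule].append(char)
                chars_rows.append({
                    "model_id": char.model_id, "rule": rule, "ddi": char.ddi,
                    "sine_amplitude": char.sine.amplitude,
                    "sine_phase": char.sine.phase, "sine_offset": char.sine.offset,
                    "response_phase": char.response_phase,
                    "symmetry": char.symmetry,
                    "probe_frequency": char.probe_frequency,
                    "probe_orientation": char.probe_orientation,
                })
    pd.DataFrame(chars_rows).to_csv(run_dir / "characterization.csv", index=False)

    summary: dict = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
                     "rules": {}}
    for rule in cfg.rules:
        summary["rules"][rule] = metrics.population_summary(
            per_rule[rule], ddi_threshold=cfg.ddi_threshold, n_boot=cfg.n_boot,
            seed=derive_seed(cfg.seed, f"boot_{rule}"),
        )
    if {"energy", "maxpool"} <= set(cfg.rules):
        e = np.array([c.ddi for c in per_rule["energy"]])
        m = np.array([c.ddi for c in per_rule["maxpool"]])
        low_e, low_m = e[e < 0.5], m[m < 0.5]
        summary["ks_distance_ddi_below_0.5"] = (
            metrics.ks_distance(low_e, low_m) if len(low_e) and len(low_m) else None
        )
    with open(out, "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
    return out


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage, resuming from persisted artifacts where possible."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        stage = "simulate"
        img_dir = stage_simulate(cfg, run_dir)
        stage = "patches"
        patches_file = stage_patches(cfg, run_dir, img_dir)
        stage = "isa"
        isa_file = stage_isa(cfg, run_dir, patches_file)
        stage = "probe"
        probe_file = stage_probe(cfg, run_dir, patches_file, isa_file)
        stage = "metrics"
        stage_metrics(cfg, run_dir, probe_file)
    except Exception as exc:
        log.error("pipeline failed in stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return run_dir
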