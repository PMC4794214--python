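"""Probe every learned complex-cell model with binocular sine gratings.

Fits a 2D Gabor to each subunit's left- and right-eye receptive field,
derives each model's probe grating (mean frequency, circular-mean
orientation), and computes 100 x 100 phase-phase response maps under the
energy and max-pooling rules.  Exports a receptive-field montage and example
response maps (with the zero-disparity diagonal overlaid) as PNGs.
"""

import argparse
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from stereoisa.pipeline import (
    desk_scale_config,
    stage_isa,
    stage_patches,
    stage_probe,
    stage_simulate,
)


def export_figures(run_dir: Path, patches_file: Path, isa_file: Path,
                   probe_file: Path, n_show: int = 16) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from stereoisa.pipeline import _pixel_filters

    filters, d, p = _pixel_filters(patches_file, isa_file)
    fig, axes = plt.subplots(4, 4, figsize=(10, 10))
    for ax, idx in zip(axes.ravel(), range(0, n_show * d, d)):
        rf = filters[idx]
        img = np.hstack([rf[: p * p].reshape(p, p), rf[p * p :].reshape(p, p)])
        ax.imshow(img, cmap="gray")
        ax.set_title(f"subspace {idx // d}, subunit 0", fontsize=8)
        ax.axis("off")
    fig.suptitle("Learned binocular receptive fields (left | right eye)")
    fig.savefig(run_dir / "receptive_fields.png", dpi=120)
    plt.close(fig)

    with h5py.File(probe_file, "r") as fh:
        names = [k for k in sorted(fh.keys()) if fh[k].attrs["probed"]][:8]
        fig, axes = plt.subplots(2, 4, figsize=(14, 7))
        for ax, name in zip(axes.ravel(), names):
            vals = fh[name]["energy"][:]
            ax.imshow(vals.T, origin="lower", extent=[-np.pi, np.pi, -np.pi, np.pi],
                      cmap="viridis")
            ax.plot([-np.pi, np.pi], [-np.pi, np.pi], "k-", lw=1)
            ax.set_title(name, fontsize=8)
            ax.set_xlabel("left phase")
            ax.set_ylabel("right phase")
        fig.suptitle("Phase-phase response maps (energy rule); black = zero disparity")
        fig.tight_layout()
        fig.savefig(run_dir / "phase_phase_maps.png", dpi=120)
        plt.close(fig)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", default="results/run_desk")
    args = ap.parse_args()

    cfg = desk_scale_config(seed=args.seed, out_dir=args.out_dir)
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    img_dir = stage_simulate(cfg, run_dir)
    patches_file = stage_patches(cfg, run_dir, img_dir)
    isa_file = stage_isa(cfg, run_dir, patches_file)
    probe_file = stage_probe(cfg, run_dir, patches_file, isa_file)

    fits = pd.read_csv(run_dir / "gabor_fits.csv")
    ok = fits[~fits["degenerate"]]
    print(f"Gabor fits: {len(fits)} halves, {len(ok)} non-degenerate")
    print(f"goodness: median {ok['goodness'].median():.2f}, "
          f"fraction > 0.5: {(ok['goodness'] > 0.5).mean():.2f}")
    print(f"fitted frequency: median {ok['frequency'].median():.3f} cyc/px")
    export_figures(run_dir, patches_file, isa_file, probe_file)
    print(f"figures: {run_dir / 'receptive_fields.png'}, "
          f"{run_dir / 'phase_phase_maps.png'}")


if __name__ == "__main__":
    main()
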