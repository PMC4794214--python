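"""Disparity selectivity of the learned models: DDI, symmetry, pooling rules.

Reduces every phase-phase map to a disparity tuning curve, fits the sine,
computes the Disparity Discrimination Index, classifies tuning symmetry
(TE / TI / Near / Far), and compares the energy and max-pooling DDI
distributions.  Writes the characterisation table, the bootstrapped
population summary, and histogram / cumulative-distribution figures.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from stereoisa.cells import ComplexCellModel
from stereoisa.gabor import ProbeParams
from stereoisa.metrics import bootstrap_histogram
from stereoisa.pipeline import (
    _pixel_filters,
    derive_seed,
    desk_scale_config,
    run_pipeline,
)
from stereoisa.probing import bar_shift_map


def export_figures(run_dir: Path, table: pd.DataFrame, seed: int) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = np.linspace(0, 1, 21)
    fig, axes = plt.subplots(1, 2, figsize=(12, 4.5))
    for ax, rule in zip(axes, ("energy", "maxpool")):
        vals = table.loc[table["rule"] == rule, "ddi"].to_numpy()
        boot = bootstrap_histogram(vals, 200, edges, seed=derive_seed(seed, f"fig_{rule}"))
        centers = (edges[:-1] + edges[1:]) / 2
        ax.bar(centers, boot["median"], width=0.045, color="steelblue")
        ax.errorbar(centers, boot["median"],
                    yerr=[boot["median"] - boot["ci_low"],
                          boot["ci_high"] - boot["median"]],
                    fmt="none", ecolor="black", capsize=2)
        ax.set_xlabel("DDI")
        ax.set_ylabel("proportion of models")
        ax.set_title(f"{rule} rule (bootstrapped 95% CI)")
    fig.tight_layout()
    fig.savefig(run_dir / "ddi_histograms.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for rule, color in (("energy", "crimson"), ("maxpool", "seagreen")):
        vals = np.sort(table.loc[table["rule"] == rule, "ddi"].to_numpy())
        ax.step(vals, np.arange(1, len(vals) + 1) / len(vals), color=color, label=rule)
    ax.set_xlabel("DDI")
    ax.set_ylabel("cumulative proportion")
    ax.legend()
    fig.tight_layout()
    fig.savefig(run_dir / "ddi_cumulative.png", dpi=120)
    plt.close(fig)


def export_bar_maps(run_dir: Path, table: pd.DataFrame, n_show: int = 4) -> None:
    """Bar-shift response maps for the highest-DDI energy models."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    filters, d, p = _pixel_filters(run_dir / "patches.h5", run_dir / "isa.h5")
    top = (table[table["rule"] == "energy"]
           .sort_values("ddi", ascending=False).head(n_show))
    fig, axes = plt.subplots(1, n_show, figsize=(4 * n_show, 4))
    for ax, (_, row) in zip(np.atleast_1d(axes), top.iterrows()):
        mid = int(row["model_id"])
        model = ComplexCellModel(subunit_filters=filters[mid * d : (mid + 1) * d],
                                 rule="energy", patch_px=p)
        probe = ProbeParams(row["probe_frequency"], row["probe_orientation"])
        rmap = bar_shift_map(model, probe)
        ax.imshow(rmap.values.T, origin="lower",
                  extent=[rmap.left_axis[0], rmap.left_axis[-1],
                          rmap.right_axis[0], rmap.right_axis[-1]], cmap="viridis")
        ax.plot(rmap.left_axis, rmap.left_axis, "k-", lw=1)
        ax.set_title(f"model {mid}, DDI {row['ddi']:.2f}", fontsize=9)
        ax.set_xlabel("left bar shift (px)")
        ax.set_ylabel("right bar shift (px)")
    fig.suptitle("Bar-shift maps of the most disparity-selective models")
    fig.tight_layout()
    fig.savefig(run_dir / "bar_shift_maps.png", dpi=120)
    plt.close(fig)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", default="results/run_desk")
    args = ap.parse_args()

    cfg = desk_scale_config(seed=args.seed, out_dir=args.out_dir)
    run_dir = run_pipeline(cfg)  # resumes from whatever 01-04 already produced

    table = pd.read_csv(run_dir / "characterization.csv")
    summary = json.loads((run_dir / "summary.json").read_text())
    for rule in ("energy", "maxpool"):
        r = summary["rules"][rule]
        print(f"[{rule}] n={r['n_models']}  max DDI={r['ddi_max']:.3f}  "
              f"95th pct={r['ddi_percentiles']['95']:.3f}  "
              f"fraction DDI>0.6: {r['fraction_ddi_above_0.6']:.2f}")
        if r["symmetry_proportions"]:
            labs = {k: f"{v['proportion']:.2f}" for k, v in
                    r["symmetry_proportions"].items() if v["proportion"] > 0}
            print(f"          symmetry among DDI>0.6 models: {labs}")
    ks = summary.get("ks_distance_ddi_below_0.5")
    if ks is None:
        print("energy vs max-pooling below DDI 0.5: too few models to compare")
    else:
        n_low = (table["ddi"] < 0.5).groupby(table["rule"]).sum().to_dict()
        print(f"energy vs max-pooling below DDI 0.5: KS distance = {ks:.3f} "
              f"(n = {n_low})")
    export_figures(run_dir, table, cfg.seed)
    export_bar_maps(run_dir, table)
    print(f"figures: {run_dir / 'ddi_histograms.png'}, "
          f"{run_dir / 'ddi_cumulative.png'}, {run_dir / 'bar_shift_maps.png'}")


if __name__ == "__main__":
    main()
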