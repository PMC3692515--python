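#!/usr/bin/env python
"""Bias and sampling error of heritability estimates by method.

Runs the replicated experiment grid (both mating regimes, all target
heritabilities and SNP panel sizes) and writes:

    results/bias_replicates.tsv   per-replicate estimates
    results/bias_summary.tsv      per-cell bias / sampling error
    results/bias_by_method.png    mean estimate vs target, per regime/method

Full scale (~7 min on one CPU): python analysis/01_bias_by_method.py
Quick look: add --replicates 5 --panel-sizes 384,1500
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from markerh2 import experiments as ex  # noqa: E402
from markerh2.config import ExperimentGrid  # noqa: E402


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--replicates", type=int, default=20)
    parser.add_argument("--panel-sizes", default="384,1500,3000,5000")
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    panels = tuple(int(x) for x in args.panel_sizes.split(","))
    grid = ExperimentGrid(panel_sizes=panels, n_replicates=args.replicates)
    table = ex.run_grid(grid, experiment_seed=args.seed)
    table.to_csv(args.out_dir / "bias_replicates.tsv", sep="\t", index=False)
    summary = ex.summarize_bias(table)
    summary.to_csv(args.out_dir / "bias_summary.tsv", sep="\t", index=False)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, S in zip(axes, sorted(summary["S"].unique())):
        sub = summary[summary["S"] == S]
        for method, grp in sub.groupby("method"):
            pooled = grp.groupby("target_h2")["mean_h2_hat"].mean()
            ax.plot(pooled.index, pooled.values, "o-", label=method)
        lims = [0, 0.7]
        ax.plot(lims, lims, "k--", lw=0.8, label="no bias")
        ax.set_title(f"S = {S}")
        ax.set_xlabel("target $h^2$")
    axes[0].set_ylabel(r"mean $\hat{h}^2$")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(args.out_dir / "bias_by_method.png", dpi=150)

    pooled = (
        table[table["converged"]]
        .assign(err=lambda d: d["h2_hat"] - d["target_h2"])
        .groupby(["S", "method"])["err"]
        .mean()
    )
    print("pooled bias by (S, method):")
    print(pooled.to_string(float_format="%+.4f"))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
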