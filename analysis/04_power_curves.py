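"""Quantify detection power for sweeps and balancing selection via ROC curves.

Forward-simulates the scenario grid (rescaled, Q = 100 by default): sweeps of
strength 2Ns introduced tau*N generations before sampling, and balanced
polymorphisms of age tau = 10N/50N/75N, each against matched neutral
comparators; scores every replicate by its maximum (windowed) CLR and sweeps
a detection threshold to trace the ROC.

Output: results/power/roc_curves.tsv, results/power/power_summary.tsv,
results/power/roc.png
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from ayescan.power_roc import balancing_power_study, power_at_fpr, sweep_power_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--reps", type=int, default=12)
    parser.add_argument("--rescale", type=float, default=100.0)
    parser.add_argument("--s2N", type=float, default=1000.0)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--out", type=Path, default=Path("results/power"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sweep = sweep_power_study(
        [0.1, 0.2, 0.5, 1.0, 2.0], args.s2N, args.reps,
        Q=args.rescale, seed=args.seed,
    )
    balancing = balancing_power_study(
        [10, 50, 75], args.reps, Q=args.rescale, seed=args.seed + 1
    )

    curves = {f"sweep_2Ns{args.s2N:.0f}_tau{tau}": c for tau, c in sweep.items()}
    curves |= {f"balancing_tau{tau}N": c for tau, c in balancing.items()}

    with (args.out / "roc_curves.tsv").open("w") as fh:
        fh.write("scenario\tfpr\ttpr\n")
        for name, curve in curves.items():
            if curve is None:
                continue
            for f, t in zip(curve.fpr, curve.tpr):
                fh.write(f"{name}\t{f:.4f}\t{t:.4f}\n")

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    with (args.out / "power_summary.tsv").open("w") as fh:
        fh.write("scenario\tauc\tpower_at_fpr05\n")
        for name, curve in curves.items():
            ax = axes[0] if name.startswith("sweep") else axes[1]
            if curve is None:
                print(f"{name}: absent (selected mutation could not fix in time)")
                fh.write(f"{name}\tNA\tNA\n")
                continue
            p05 = power_at_fpr(curve, 0.05)
            print(f"{name}: AUC={curve.auc:.3f}, power@FPR=0.05: {p05:.2f}")
            fh.write(f"{name}\t{curve.auc:.4f}\t{p05:.4f}\n")
            ax.plot(curve.fpr, curve.tpr, label=name, drawstyle="steps-post")
    for ax, title in zip(axes, ("selective sweeps", "balancing selection")):
        ax.plot([0, 1], [0, 1], "k:", lw=0.7)
        ax.set_xlabel("FPR")
        ax.set_title(title)
        ax.legend(fontsize=6)
    axes[0].set_ylabel("TPR")
    fig.tight_layout()
    fig.savefig(args.out / "roc.png", dpi=120)
    print(f"wrote ROC tables and figure under {args.out}")


if __name__ == "__main__":
    main()
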