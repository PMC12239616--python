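"""Contrast the calibrated thresholds with a conventional 5%-tail outlier scan.

Pools the neutral-baseline scan values produced by 02_calibrate_thresholds.py
— data containing no episodic selection whatsoever — and compares how many
positions/windows each approach flags: the empirical 5% tail necessarily
flags ~5% of them, while the simulation-calibrated maximum-CLR threshold
flags none.

Output: results/outlier_contrast.tsv
"""

import argparse
from pathlib import Path

import numpy as np

from ayescan.calibration import empirical_tail_quantile


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scans", type=Path, default=Path("results/null_scans"))
    parser.add_argument("--thresholds", type=Path, default=Path("results/thresholds.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/outlier_contrast.tsv"))
    args = parser.parse_args()

    thresholds = {}
    for line in args.thresholds.read_text().splitlines()[1:]:
        scheme, value = line.split("\t")
        thresholds[scheme] = float(value)

    rows = []
    for scheme, threshold in thresholds.items():
        pooled = []
        for path in sorted(args.scans.glob(f"{scheme}.*.tsv")):
            values = [
                float(line.split("\t")[1])
                for line in path.read_text().splitlines()[1:]
            ]
            pooled.extend(values)
        pooled = np.array(pooled)
        cutoff, n_tail = empirical_tail_quantile(pooled, 0.05)
        n_calibrated = int((pooled > threshold).sum())
        rows.append((scheme, pooled.size, cutoff, n_tail, threshold, n_calibrated))
        print(
            f"{scheme}: {pooled.size} neutral values | 5% tail flags {n_tail} "
            f"(cutoff {cutoff:.2f}) | calibrated threshold {threshold:.2f} "
            f"flags {n_calibrated}"
        )

    with args.out.open("w") as fh:
        fh.write(
            "scheme\tn_values\ttail_cutoff\ttail_flagged\t"
            "calibrated_threshold\tcalibrated_flagged\n"
        )
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


if __name__ == "__main__":
    main()
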