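"""Scan the neutral baseline and set conservative genome-wide null thresholds.

Runs the per-SNP sweep CLR scan and the balancing-selection scan (10-SNP
windows, step 5, and 100-SNP windows, step 50) on every neutral replicate
from 01_simulate_null.py, then sets each scheme's threshold to the single
highest CLR observed anywhere — the largest value the baseline model
produces without episodic selection.

Output: results/thresholds.tsv, results/null_scans/<scheme>.<replicate>.tsv
"""

import argparse
from pathlib import Path

from ayescan.balance_clr import scan_balancing
from ayescan.calibration import null_thresholds
from ayescan.io_formats import read_freq_file, read_spectrum_file
from ayescan.sfs_stats import FoldedSFS
from ayescan.sweep_clr import SweepScanTable, scan_sweep

SCHEMES = {"sweep": None, "b0maf_w10": (10, 5), "b0maf_w100": (100, 50)}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--null", type=Path, default=Path("results/null"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    G = FoldedSFS(10, read_spectrum_file(args.null / "background.spect", 10))
    table = SweepScanTable(G)
    scans_dir = args.out / "null_scans"
    scans_dir.mkdir(parents=True, exist_ok=True)

    collections = {scheme: [] for scheme in SCHEMES}
    for freq_path in sorted(args.null.glob("*.freq")):
        records = read_freq_file(freq_path)
        tag = freq_path.stem
        for scheme, ws in SCHEMES.items():
            if ws is None:
                results = scan_sweep(records, G, table=table)
            else:
                results = scan_balancing(records, ws[0], ws[1], G)
            clrs = [r.clr for r in results]
            collections[scheme].append(clrs)
            with (scans_dir / f"{scheme}.{tag}.tsv").open("w") as fh:
                fh.write("position\tCLR\n")
                for r in results:
                    fh.write(f"{r.position:.1f}\t{r.clr:.6f}\n")

    thresholds = null_thresholds(
        {k: v for k, v in collections.items() if any(len(c) for c in v)}
    )
    with (args.out / "thresholds.tsv").open("w") as fh:
        fh.write("scheme\tthreshold\n")
        for scheme, value in thresholds.items():
            fh.write(f"{scheme}\t{value:.6f}\n")
            print(f"{scheme}: null threshold (max CLR over replicates) = {value:.3f}")


if __name__ == "__main__":
    main()
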