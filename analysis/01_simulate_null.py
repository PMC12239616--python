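"""Simulate the neutral demographic baseline used to calibrate null thresholds.

Generates coalescent replicates of toy chromosomes under the bottleneck
demography (ancestral N = 23,706, ancient and recent declines) with the fixed
rates mu = 1.52e-8 and r = 1 cM/Mb, samples 5 diploids, folds, and writes one
freq file per replicate plus the pooled background spectrum (SpectFile).

Output: results/null/<chrom>.rep<k>.freq, results/null/background.spect
"""

import argparse
from pathlib import Path

from ayescan.demography import PiecewiseDemography, neutral_chromosome_replicate
from ayescan.forward_sim import MU_FIXED, REC_FIXED
from ayescan.io_formats import write_freq_file, write_spectrum_file
from ayescan.sfs_stats import background_spectrum


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--chromosomes", type=int, default=2)
    parser.add_argument("--replicates", type=int, default=15)
    parser.add_argument("--length", type=int, default=91_161,
                        help="replicate length; keep matched to the scanned "
                        "chromosomes, since composite CLR magnitudes grow "
                        "with the number of sites")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/null"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    model = PiecewiseDemography.default_aye_aye()
    pooled = []
    n_files = 0
    for c in range(args.chromosomes):
        for k in range(args.replicates):
            rep = neutral_chromosome_replicate(
                model, args.length, MU_FIXED, REC_FIXED, 10,
                seed=args.seed + 1000 * c + k, chrom=f"chr{c + 1}",
            )
            write_freq_file(rep.records, args.out / f"chr{c + 1}.rep{k:02d}.freq")
            pooled.extend(rep.records)
            n_files += 1

    G = background_spectrum(pooled)
    write_spectrum_file(10, G.probs, args.out / "background.spect")
    print(
        f"wrote {n_files} neutral replicates ({len(pooled)} SNPs pooled) "
        f"under {args.out}"
    )
    print("background folded SFS:", ", ".join(f"{p:.4f}" for p in G.probs))


if __name__ == "__main__":
    main()
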