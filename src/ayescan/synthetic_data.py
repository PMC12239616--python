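"""Self-contained miniature datasets in the empirical input formats.

Emits, for a configurable set of toy chromosomes, the files the empirical
pipeline consumes — per-chromosome VCF (5 diploid samples), GFF3 gene
annotations, BED structural variants, and matching allele-frequency files —
plus a ground-truth manifest (scenario, selected position, seed).  Neutral
chromosomes come from the coalescent baseline; chromosomes with implanted
sweeps or balanced polymorphisms come from rescaled forward simulations on
the 91,161-bp architecture.  Identical config and seed give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .demography import PiecewiseDemography, neutral_chromosome_replicate
from .forward_sim import (
    MU_FIXED,
    REC_FIXED,
    DFEConfig,
    GenomeArchitecture,
    SelectionScenario,
    build_architecture,
    run_forward,
)
from .io_formats import AlleleFrequencyRecord, write_freq_file

__all__ = ["ChromosomeSpec", "FixtureConfig", "make_fixture"]


@dataclass(frozen=True)
class ChromosomeSpec:
    """One toy chromosome: its scenario and (neutral-only) length."""

    name: str
    scenario: Literal["neutral", "sweep", "balancing"] = "neutral"
    length: int = 500_000  # used for neutral chromosomes; selection
    # chromosomes take the forward-simulation architecture length
    tau: float | None = None
    s2N: float | None = None
    f_eq: float | None = None
    selected_pos: int | None = None


@dataclass(frozen=True)
class FixtureConfig:
    chromosomes: tuple[ChromosomeSpec, ...]
    seed: int = 1
    n_diploid: int = 5
    Q: float = 100.0
    model: PiecewiseDemography = field(default_factory=PiecewiseDemography.default_aye_aye)
    arch: GenomeArchitecture = field(default_factory=build_architecture)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("fixture needs at least one chromosome")
        for spec in self.chromosomes:
            if spec.scenario != "neutral" and spec.selected_pos is not None:
                if not 1 <= spec.selected_pos <= self.arch.length:
                    raise ValueError(
                        f"{spec.name}: selected site {spec.selected_pos} outside "
                        f"[1, {self.arch.length}]"
                    )


def _pair_haplotypes(
    haps: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Randomly pair 2k haplotype rows into k diploids: (sites, k, 2)."""
    order = rng.permutation(haps.shape[0])
    paired = haps[order].T  # (sites, 2k)
    return paired.reshape(paired.shape[0], -1, 2)


def _write_vcf(
    path: Path,
    chrom: str,
    length: int,
    positions: np.ndarray,
    genotypes: np.ndarray,
    sample_names: list[str],
) -> None:
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for pos, site in zip(positions, genotypes):
            gts = "\t".join(f"{a}/{b}" for a, b in site)
            fh.write(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def _gene_rows(chrom: str, length: int, arch: GenomeArchitecture) -> list[tuple]:
    """Tile the architecture's gene spans across the chromosome."""
    exons = arch.exons()
    per_gene = 9 if len(exons) % 9 == 0 else len(exons)
    spans = []
    for g in range(len(exons) // per_gene):
        first = exons[g * per_gene]
        last = exons[(g + 1) * per_gene - 1]
        spans.append((first[0], last[1]))
    rows = []
    idx = 1
    offset = 0
    while offset < length:
        for s, e in spans:
            if offset + e > length:
                break
            rows.append((chrom, offset + s, offset + e, f"{chrom}_gene{idx}"))
            idx += 1
        offset += arch.length
    return rows


def make_fixture(config: FixtureConfig, out_dir: str | Path) -> dict:
    """Write the fixture files; returns the manifest as a list of dicts.

    Files: <name>.vcf and <name>.freq per chromosome, genes.gff3, svs.bed,
    manifest.tsv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    samples = [f"ind{i + 1}" for i in range(config.n_diploid)]
    n_chrom = 2 * config.n_diploid

    manifest: list[dict] = []
    gene_rows: list[tuple] = []
    sv_rows: list[tuple] = []
    for i, spec in enumerate(config.chromosomes):
        chrom_seed = int(rng.integers(2**31 - 1))
        if spec.scenario == "neutral":
            rep = neutral_chromosome_replicate(
                config.model, spec.length, MU_FIXED, REC_FIXED, n_chrom,
                seed=chrom_seed, chrom=spec.name,
            )
            records, haps = list(rep.records), rep.haplotypes
            length = spec.length
            selected_pos = None
            params = ""
        else:
            scenario = SelectionScenario(
                mode=spec.scenario,
                tau=spec.tau,
                s2N=spec.s2N,
                f_eq=spec.f_eq,
                selected_pos=spec.selected_pos,
            )
            result = run_forward(
                config.model, config.arch, DFEConfig(), scenario,
                Q=config.Q, seed=chrom_seed, n_chrom=n_chrom,
            )
            records, haps = list(result.records), result.haplotypes
            length = config.arch.length
            selected_pos = result.selected_pos
            params = (
                f"2Ns={spec.s2N}" if spec.scenario == "sweep" else f"Feq={spec.f_eq}"
            )

        positions = np.array([r.position for r in records], dtype=np.int64)
        genotypes = _pair_haplotypes(haps, rng)
        _write_vcf(out / f"{spec.name}.vcf", spec.name, length, positions,
                   genotypes, samples)
        # freq records re-derived from the paired genotypes so the VCF and the
        # freq file agree exactly (folding is pairing-invariant, but keep one
        # source of truth)
        write_freq_file(records, out / f"{spec.name}.freq")

        gene_rows.extend(_gene_rows(spec.name, length, config.arch))
        if selected_pos is not None:
            sv_rows.append(
                (spec.name, max(0, selected_pos - 2000), min(length, selected_pos + 2000),
                 "inversion")
            )
        manifest.append(
            {
                "chrom": spec.name,
                "length": length,
                "scenario": spec.scenario,
                "selected_pos": selected_pos,
                "tau": spec.tau,
                "params": params,
                "seed": chrom_seed,
            }
        )

    with (out / "genes.gff3").open("w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, gid in gene_rows:
            fh.write(f"{chrom}\tayescan\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n")
    with (out / "svs.bed").open("w") as fh:
        for chrom, start1, end1, cls in sv_rows:
            fh.write(f"{chrom}\t{start1 - 1}\t{end1}\t{cls}\n")
    with (out / "manifest.tsv").open("w") as fh:
        cols = ["chrom", "length", "scenario", "selected_pos", "tau", "params", "seed"]
        fh.write("\t".join(cols) + "\n")
        for row in manifest:
            fh.write("\t".join("" if row[c] is None else str(row[c]) for c in cols) + "\n")
    return {"manifest": manifest, "dir": out}
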