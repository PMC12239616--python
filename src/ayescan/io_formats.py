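"""Readers and writers for every external file the pipeline touches.

Formats: whitespace-delimited allele-frequency files (one row per polymorphic
site: position, minor-allele count x, sample size n, folded flag), two-column
spectrum files, grid files (one test position per line), tab-delimited scan
outputs, VCF-derived SNP tables, GFF3 gene annotations, and BED
structural-variant intervals.

Coordinates are 1-based throughout; BED input (0-based half-open) is converted
on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "ConfigurationError",
    "AlleleFrequencyRecord",
    "GeneInterval",
    "SVInterval",
    "read_freq_file",
    "write_freq_file",
    "variant_table_to_freq",
    "vcf_to_freq",
    "read_gene_annotations",
    "read_sv_intervals",
    "read_spectrum_file",
    "write_spectrum_file",
    "read_grid_file",
    "write_grid_file",
]

FREQ_HEADER = ("position", "x", "n", "folded")


class FormatError(ValueError):
    """A file did not conform to its expected dialect."""


class ConfigurationError(ValueError):
    """Inputs inconsistent with the pipeline configuration."""


@dataclass(frozen=True)
class AlleleFrequencyRecord:
    """One polymorphic site: 1-based position, folded minor count x of n."""

    position: int
    x: int
    n: int
    folded: bool = True

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not 1 <= self.x <= self.n // 2:
            raise ValueError(
                f"folded count {self.x} outside [1, {self.n // 2}] for n={self.n}"
            )


@dataclass(frozen=True)
class GeneInterval:
    """A gene feature: 1-based closed interval on a chromosome."""

    chrom: str
    start: int
    end: int
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class SVInterval:
    """A structural variant: 1-based closed interval (converted from BED)."""

    chrom: str
    start: int
    end: int
    sv_class: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"SV interval start {self.start} > end {self.end}")


def read_freq_file(path: str | Path) -> list[AlleleFrequencyRecord]:
    """Read an allele-frequency file (header: position x n folded)."""
    path = Path(path)
    records: list[AlleleFrequencyRecord] = []
    with path.open() as fh:
        header = fh.readline()
        if tuple(header.split()) != FREQ_HEADER:
            raise FormatError(
                f"{path}:1: expected header {' '.join(FREQ_HEADER)!r}, "
                f"got {header.strip()!r}"
            )
        last_pos = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            try:
                position, x, n, folded = (int(f) for f in fields)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field: {exc}") from exc
            if folded not in (0, 1):
                raise FormatError(f"{path}:{lineno}: folded flag must be 0/1, got {folded}")
            if position <= last_pos:
                raise FormatError(
                    f"{path}:{lineno}: positions must be strictly increasing "
                    f"({position} after {last_pos})"
                )
            try:
                rec = AlleleFrequencyRecord(position, x, n, bool(folded))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
            last_pos = position
    return records


def write_freq_file(records: Sequence[AlleleFrequencyRecord], path: str | Path) -> None:
    """Write records to a freq file; positions must be strictly increasing."""
    positions = [r.position for r in records]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("records must have strictly increasing, unique positions")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(" ".join(FREQ_HEADER) + "\n")
        for r in records:
            fh.write(f"{r.position} {r.x} {r.n} {int(r.folded)}\n")


def variant_table_to_freq(
    positions: np.ndarray,
    genotypes: np.ndarray,
    *,
    n_diploid: int = 5,
) -> list[AlleleFrequencyRecord]:
    """Fold a biallelic diploid genotype table into allele-frequency records.

    ``genotypes`` has shape (sites, n_diploid, 2) with entries 0/1 for
    reference/alternate and -1 for a missing allele call.  Sites with any
    missing call (allele number < 2*n_diploid) are dropped, as are monomorphic
    sites; the rest are emitted with x = min(c, 2*n_diploid - c).
    """
    genotypes = np.asarray(genotypes)
    positions = np.asarray(positions)
    if genotypes.ndim != 3 or genotypes.shape[2] != 2:
        raise ConfigurationError(
            f"genotype table must have shape (sites, samples, 2), got {genotypes.shape}"
        )
    if genotypes.shape[1] != n_diploid:
        raise ConfigurationError(
            f"expected {n_diploid} diploid samples, got {genotypes.shape[1]}"
        )
    n = 2 * n_diploid
    out: list[AlleleFrequencyRecord] = []
    for pos, site in zip(positions, genotypes):
        if np.any(site < 0):  # incomplete genotyping: drop (AN < n filter)
            continue
        c = int(site.sum())
        if c == 0 or c == n:
            continue
        out.append(AlleleFrequencyRecord(int(pos), min(c, n - c), n))
    return out


def vcf_to_freq(
    path: str | Path, *, n_diploid: int = 5, chrom: str | None = None
) -> list[AlleleFrequencyRecord]:
    """Read a VCF and fold its biallelic SNPs into allele-frequency records.

    Multiallelic sites are dropped; sites with any missing genotype are
    dropped (complete-genotyping filter); monomorphic sites are dropped.
    """
    import pysam

    records: list[AlleleFrequencyRecord] = []
    n = 2 * n_diploid
    with pysam.VariantFile(str(path)) as vcf:
        n_samples = len(vcf.header.samples)
        if n_samples != n_diploid:
            raise ConfigurationError(
                f"expected {n_diploid} samples in VCF, found {n_samples}"
            )
        for site in vcf:
            if chrom is not None and site.chrom != chrom:
                continue
            if site.alts is None or len(site.alts) != 1:
                continue
            alleles: list[int] = []
            for sample in site.samples.values():
                gt = sample["GT"]
                alleles.extend(-1 if a is None else a for a in gt)
            if len(alleles) != n or any(a < 0 for a in alleles):
                continue
            c = sum(alleles)
            if c == 0 or c == n:
                continue
            records.append(AlleleFrequencyRecord(site.pos, min(c, n - c), n))
    return records


def read_gene_annotations(path: str | Path) -> list[GeneInterval]:
    """Extract gene features (with their ID) from a GFF3 file."""
    import gffutils

    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted errors on bad input
        raise FormatError(f"{path}: malformed GFF3: {exc}") from exc
    genes: list[GeneInterval] = []
    for feat in db.features_of_type("gene", order_by="start"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        try:
            genes.append(GeneInterval(feat.seqid, feat.start, feat.end, gene_id))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return genes


def read_sv_intervals(path: str | Path) -> list[SVInterval]:
    """Read structural variants from BED (0-based half-open -> 1-based closed)."""
    path = Path(path)
    out: list[SVInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start0 < 0 or end0 < 0:
                raise FormatError(f"{path}:{lineno}: negative coordinate")
            if end0 < start0:
                raise FormatError(f"{path}:{lineno}: end {end0} < start {start0}")
            sv_class = fields[3].strip() if len(fields) > 3 else "SV"
            out.append(SVInterval(chrom, start0 + 1, end0, sv_class))
    return out


def write_spectrum_file(n: int, probs: np.ndarray, path: str | Path) -> None:
    """Persist a folded spectrum as two columns: class k, probability."""
    if len(probs) != n // 2:
        raise ValueError(f"expected {n // 2} classes for n={n}, got {len(probs)}")
    with Path(path).open("w") as fh:
        for k, p in enumerate(np.asarray(probs, dtype=float), start=1):
            fh.write(f"{k}\t{p:.17g}\n")


def read_spectrum_file(path: str | Path, n: int) -> np.ndarray:
    """Read a two-column folded spectrum file for sample size n."""
    path = Path(path)
    probs = np.zeros(n // 2)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            k = int(fields[0])
            if not 1 <= k <= n // 2:
                raise FormatError(f"{path}:{lineno}: class {k} outside [1, {n // 2}]")
            probs[k - 1] = float(fields[1])
    if abs(probs.sum() - 1.0) > 1e-6:
        raise FormatError(f"{path}: spectrum sums to {probs.sum()}, expected 1")
    return probs


def read_grid_file(path: str | Path) -> np.ndarray:
    """Read test positions (one integer per line)."""
    return np.loadtxt(Path(path), dtype=np.int64, ndmin=1)


def write_grid_file(positions: Iterable[int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for p in positions:
            fh.write(f"{int(p)}\n")
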