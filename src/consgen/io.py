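"""Genotype containers and readers.

The canonical in-memory object is :class:`GenotypeMatrix`: an individuals x
biallelic-SNP matrix of genotype codes (0 = hom-ref, 1 = het, 2 = hom-alt,
``MISSING`` = -1) together with a :class:`VariantTable` of chromosome /
position / allele metadata. Genotypes are unphased throughout; phase
separators in VCF are read but ignored. Positions are 1-based (VCF
convention) internally; BED output elsewhere in the package converts to
0-based half-open coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel genotype code for a missing call. Never conflated with hom-ref.
MISSING: int = -1

#: Chicken autosomal karyotype used by default: gga1..gga28.
CHICKEN_AUTOSOMES: tuple[str, ...] = tuple(f"gga{i}" for i in range(1, 29))


class GenotypeIOError(ValueError):
    """Malformed genotype input (bad VCF/TSV content, ragged rows, ...)."""


@dataclass
class VariantTable:
    """Per-SNP metadata: chromosome label, 1-based position, REF/ALT alleles."""

    chromosome: np.ndarray  # dtype=object (str labels)
    position: np.ndarray  # int64, 1-based
    ref_allele: np.ndarray  # dtype=object
    alt_allele: np.ndarray  # dtype=object

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        n = len(self.position)
        if not (len(self.chromosome) == len(self.ref_allele) == len(self.alt_allele) == n):
            raise GenotypeIOError("variant table columns have unequal lengths")

    @property
    def n_variants(self) -> int:
        return len(self.position)

    def chromosomes(self) -> list[str]:
        """Distinct chromosome labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.chromosome:
            seen.setdefault(c, None)
        return list(seen)

    def subset(self, index: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.chromosome[index],
            self.position[index],
            self.ref_allele[index],
            self.alt_allele[index],
        )

    def validate(self) -> None:
        """Positions must be strictly increasing within each chromosome."""
        for chrom in self.chromosomes():
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise GenotypeIOError(
                    f"positions not strictly increasing on {chrom}"
                )


@dataclass
class GenotypeMatrix:
    """Unphased diploid genotypes for a panel of samples.

    ``calls[i, j]`` is the genotype code of sample ``i`` at variant ``j``.
    """

    samples: list[str]
    variants: VariantTable
    calls: np.ndarray  # int8, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), self.variants.n_variants):
            raise GenotypeIOError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {self.variants.n_variants} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeIOError("genotype codes must be 0/1/2 or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return self.variants.n_variants

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.samples, self.variants.subset(index), self.calls[:, index])

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in names if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = np.array([lookup[s] for s in names], dtype=np.intp)
        return GenotypeMatrix(list(names), self.variants, self.calls[idx])

    def genotype_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-variant (n_hom_ref, n_het, n_hom_alt, n_missing)."""
        c = self.calls
        return (
            (c == 0).sum(axis=0),
            (c == 1).sum(axis=0),
            (c == 2).sum(axis=0),
            (c == MISSING).sum(axis=0),
        )

    def allele_frequencies(self) -> np.ndarray:
        """Per-variant ALT allele frequency among called alleles (NaN if none)."""
        n0, n1, n2, _ = self.genotype_counts()
        called = n0 + n1 + n2
        with np.errstate(invalid="ignore"):
            return np.where(called > 0, (2.0 * n2 + n1) / (2.0 * called), np.nan)


@dataclass
class SubpopulationMap:
    """Assignment of samples to sub-populations (breed x generation), optional sex."""

    subpop: dict[str, str]
    sex: dict[str, str] = field(default_factory=dict)

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.subpop.values():
            seen.setdefault(v, None)
        return list(seen)

    def samples_in(self, label: str) -> list[str]:
        return [s for s, lab in self.subpop.items() if lab == label]


def _canonical_variant_order(chrom: np.ndarray, pos: np.ndarray, karyotype: Sequence[str]) -> np.ndarray:
    rank = {c: i for i, c in enumerate(karyotype)}
    keys = np.array([rank[c] for c in chrom], dtype=np.int64)
    return np.lexsort((pos, keys))


def read_vcf(
    path: str | Path,
    karyotype: Sequence[str] = CHICKEN_AUTOSOMES,
    strict: bool = False,
) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and indel records are skipped (counts logged). Records on
    chromosomes outside ``karyotype`` are skipped with a warning, or raise in
    ``strict`` mode — this is how sex chromosomes and unplaced scaffolds are
    excluded when an autosomal karyotype is declared. Variants are returned
    sorted by (chromosome, position) in karyotype order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped_nonsnp = 0
    n_skipped_chrom = 0
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    code_map = np.array([0, 1, MISSING, 2], dtype=np.int8)
    allowed = set(karyotype)
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped_nonsnp += 1
            continue
        if rec.CHROM not in allowed:
            if strict:
                raise GenotypeIOError(f"unknown chromosome {rec.CHROM!r} at position {rec.POS}")
            n_skipped_chrom += 1
            continue
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        columns.append(code_map[np.asarray(rec.gt_types, dtype=np.intp)])
    vcf.close()
    if n_skipped_nonsnp:
        logger.info("skipped %d non-biallelic-SNP records", n_skipped_nonsnp)
    if n_skipped_chrom:
        warnings.warn(
            f"skipped {n_skipped_chrom} records on chromosomes outside the declared karyotype",
            stacklevel=2,
        )
    if not columns:
        raise GenotypeIOError(f"no biallelic SNP records read from {path}")
    calls = np.stack(columns, axis=1)
    vt = VariantTable(np.array(chroms, dtype=object), np.array(positions), np.array(refs, dtype=object), np.array(alts, dtype=object))
    order = _canonical_variant_order(vt.chromosome, vt.position, list(karyotype))
    gm = GenotypeMatrix(samples, vt.subset(order), calls[:, order])
    gm.variants.validate()
    return gm


def read_matrix_tsv(path: str | Path, karyotype: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read the package's tabular genotype dialect.

    Header: ``chrom pos ref alt <sample1> <sample2> ...``; one row per SNP;
    genotype cells are 0/1/2 or ``.`` for missing. Semantics are identical to
    :func:`read_vcf` output. Rows out of positional order are sorted with a
    warning.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["chrom", "pos", "ref", "alt"]:
            raise GenotypeIOError(f"{path}: expected header starting 'chrom pos ref alt'")
        samples = header[4:]
        ncol = len(header)
        chroms, positions, refs, alts, rows = [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise GenotypeIOError(f"{path}: ragged row at line {lineno}")
            chroms.append(parts[0])
            positions.append(int(parts[1]))
            refs.append(parts[2])
            alts.append(parts[3])
            rows.append([MISSING if cell == "." else int(cell) for cell in parts[4:]])
    if not rows:
        raise GenotypeIOError(f"{path}: no variant rows")
    calls = np.array(rows, dtype=np.int8).T
    vt = VariantTable(np.array(chroms, dtype=object), np.array(positions), np.array(refs, dtype=object), np.array(alts, dtype=object))
    kary = list(karyotype) if karyotype is not None else vt.chromosomes()
    order = _canonical_variant_order(vt.chromosome, vt.position, kary)
    if not np.array_equal(order, np.arange(len(order))):
        warnings.warn(f"{path}: variants not sorted by (chromosome, position); sorting", stacklevel=2)
    gm = GenotypeMatrix(samples, vt.subset(order), calls[:, order])
    gm.variants.validate()
    return gm


def write_matrix_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the tabular genotype dialect read by :func:`read_matrix_tsv`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["chrom", "pos", "ref", "alt", *gm.samples]) + "\n")
        vt = gm.variants
        for j in range(gm.n_variants):
            cells = ["." if c == MISSING else str(int(c)) for c in gm.calls[:, j]]
            fh.write(
                "\t".join([vt.chromosome[j], str(int(vt.position[j])), vt.ref_allele[j], vt.alt_allele[j], *cells])
                + "\n"
            )


def read_subpopulation_tsv(path: str | Path) -> SubpopulationMap:
    """Two-column TSV (sample, subpop) with optional third column sex in {M,F}."""
    subpop: dict[str, str] = {}
    sex: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GenotypeIOError(f"{path}: need at least 2 columns at line {lineno}")
            subpop[parts[0]] = parts[1]
            if len(parts) >= 3 and parts[2]:
                if parts[2] not in ("M", "F"):
                    raise GenotypeIOError(f"{path}: sex must be M or F at line {lineno}")
                sex[parts[0]] = parts[2]
    return SubpopulationMap(subpop, sex)


def write_subpopulation_tsv(smap: SubpopulationMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s, lab in smap.subpop.items():
            sx = smap.sex.get(s, "")
            fh.write(f"{s}\t{lab}" + (f"\t{sx}" if sx else "") + "\n")


def split_by_subpopulation(gm: GenotypeMatrix, smap: SubpopulationMap) -> dict[str, GenotypeMatrix]:
    """Partition samples into one GenotypeMatrix per sub-population.

    Sample order within each view follows the order in ``gm``. Every mapped
    sample must be present; samples in ``gm`` but not in the map raise.
    """
    if not smap.subpop:
        raise ValueError("empty sub-population map")
    present = set(gm.samples)
    unmapped_in_gm = [s for s in gm.samples if s not in smap.subpop]
    if unmapped_in_gm:
        raise ValueError(f"samples without sub-population assignment: {unmapped_in_gm}")
    absent = [s for s in smap.subpop if s not in present]
    if absent:
        raise ValueError(f"mapped samples not present in genotype matrix: {absent}")
    out: dict[str, GenotypeMatrix] = {}
    for label in smap.labels():
        names = [s for s in gm.samples if smap.subpop[s] == label]
        out[label] = gm.subset_samples(names)
    return out
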