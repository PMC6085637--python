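"""Forward-in-time simulation of a closed conserved flock.

Simulates discrete, non-overlapping generations of a two-sex flock kept at a
constant census of ``n_males`` sires and ``n_females`` dams under one of
three replacement schemes:

* ``RR`` — random mating and random selection: every replacement breeder is
  produced from a uniformly drawn sire and dam.
* ``RF`` — random mating with family equalization: exactly one son is
  retained per sire family and one daughter per dam family; dams are
  re-partitioned evenly among the new sires at random each generation.
* ``FR`` — family rotational mating: dam families are fixed; family *i*'s
  replacement sire is a son born in family *i - 1* (mod n_males).

Founders are drawn in linkage equilibrium from a uniform MAF distribution.
Gametes recombine with Poisson crossovers (no interference) at a per-
chromosome rate of length_Mb x cM_per_Mb / 100 Morgans; there is no
mutation (drift dominates on the few-dozen-generation time scales of
interest). Offspring sex is independent with probability 1/2; sexes are
re-drawn as needed to satisfy the retention quotas, which is realised here
by generating sons and daughters directly for their slots.

The full pedigree is tracked so that genomic statistics can be validated
against pedigree expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .inbreeding import MatingPlan
from .io import GenotypeMatrix, SubpopulationMap, VariantTable
from .pedigree import UNKNOWN, Pedigree

__all__ = [
    "ChromosomeSpec",
    "SimConfig",
    "SimResult",
    "simulate_flock",
    "StudyFixture",
    "generate_study_fixture",
]


@dataclass
class ChromosomeSpec:
    label: str
    length_bp: int
    n_snps: int
    cm_per_mb: float = 3.0  # chicken-like macrochromosome order of magnitude

    @property
    def morgans(self) -> float:
        return self.length_bp / 1e6 * self.cm_per_mb / 100.0


def default_genome(
    n_chromosomes: int = 5,
    snps_per_chromosome: int = 1_000,
    length_bp: int = 20_000_000,
    cm_per_mb: float = 3.0,
) -> list[ChromosomeSpec]:
    return [
        ChromosomeSpec(f"gga{i + 1}", length_bp, snps_per_chromosome, cm_per_mb)
        for i in range(n_chromosomes)
    ]


@dataclass
class SimConfig:
    n_males: int = 30
    n_females: int = 300
    n_generations: int = 17
    scheme: Literal["RR", "RF", "FR"] = "RF"
    genome: list[ChromosomeSpec] = field(default_factory=default_genome)
    founder_maf: tuple[float, float] = (0.05, 0.5)
    sample_generations: tuple[int, ...] = ()
    sample_males: int = 10
    sample_females: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_males < 1 or self.n_females < 1 or self.n_males > self.n_females:
            raise ValueError("need 1 <= n_males <= n_females")
        if self.scheme not in ("RR", "RF", "FR"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if any(c.n_snps < 1 for c in self.genome):
            raise ValueError("every chromosome needs at least one SNP")
        if any(g > self.n_generations for g in self.sample_generations):
            raise ValueError("cannot sample beyond the simulated horizon")
        if self.sample_generations and (
            self.sample_males > self.n_males or self.sample_females > self.n_females
        ):
            raise ValueError("sample sizes exceed the breeding census")


@dataclass
class SimResult:
    config: SimConfig
    pedigree: Pedigree
    samples: dict[int, GenotypeMatrix]  # generation -> sampled genotypes
    sample_sex: dict[int, dict[str, str]]
    final_haplotypes: list[np.ndarray]  # per chromosome, (2N, n_snps) for the last generation


class _Flock:
    """Breeding population state: haplotypes per chromosome + pedigree rows."""

    def __init__(
        self,
        cfg: SimConfig,
        rng: np.random.Generator,
        id_prefix: str = "I",
        positions: list[np.ndarray] | None = None,
        founder_freqs: list[np.ndarray] | None = None,
    ):
        self.cfg = cfg
        self.rng = rng
        self.prefix = id_prefix
        nm, nf = cfg.n_males, cfg.n_females
        n = nm + nf
        self.positions = positions if positions is not None else [
            np.sort(rng.choice(np.arange(1, c.length_bp + 1), size=c.n_snps, replace=False))
            for c in cfg.genome
        ]
        freqs = (
            founder_freqs
            if founder_freqs is not None
            else [rng.uniform(*cfg.founder_maf, size=c.n_snps) for c in cfg.genome]
        )
        self.haps = [
            (rng.random((2 * n, c.n_snps)) < f).astype(np.int8)
            for c, f in zip(cfg.genome, freqs)
        ]
        self.founder_freqs = freqs
        # pedigree: rows 0..n-1 are founders; sires first, then dams
        self.ped_ids: list[str] = [f"{id_prefix}G0_{k:04d}" for k in range(n)]
        self.ped_sire: list[int] = [UNKNOWN] * n
        self.ped_dam: list[int] = [UNKNOWN] * n
        self.ped_sex: list[str] = ["M"] * nm + ["F"] * nf
        self.ped_gen: list[int] = [0] * n
        self.rows = np.arange(n)  # pedigree row per current breeder
        # family of each dam (index of her sire), used by RF / FR
        self.fam_of_dam = self._even_partition()

    def _even_partition(self) -> np.ndarray:
        nm, nf = self.cfg.n_males, self.cfg.n_females
        base = np.repeat(np.arange(nm), int(np.ceil(nf / nm)))[:nf]
        return self.rng.permutation(base)

    def _gamete(self, chrom: int, parent_slot: int) -> np.ndarray:
        spec = self.cfg.genome[chrom]
        pos = self.positions[chrom]
        h0 = self.haps[chrom][2 * parent_slot]
        h1 = self.haps[chrom][2 * parent_slot + 1]
        phase = int(self.rng.integers(0, 2))
        n_cx = int(self.rng.poisson(spec.morgans))
        if n_cx == 0:
            return (h0 if phase == 0 else h1).copy()
        gam = (h0 if phase == 0 else h1).copy()
        cuts = np.searchsorted(pos, np.sort(self.rng.uniform(1, spec.length_bp, n_cx)))
        for cut in cuts:
            phase = 1 - phase
            gam[cut:] = (h0 if phase == 0 else h1)[cut:]
        return gam

    def _make_offspring(self, sire_slots: np.ndarray, dam_slots: np.ndarray, sexes: list[str], gen: int):
        """Produce one offspring per (sire, dam) pair; returns new haplotype
        arrays and appends pedigree rows."""
        n_off = len(sire_slots)
        new_haps = [np.empty((2 * n_off, c.n_snps), dtype=np.int8) for c in self.cfg.genome]
        for k in range(n_off):
            for c in range(len(self.cfg.genome)):
                new_haps[c][2 * k] = self._gamete(c, int(sire_slots[k]))
                new_haps[c][2 * k + 1] = self._gamete(c, int(dam_slots[k]))
        start = len(self.ped_ids)
        for k in range(n_off):
            self.ped_ids.append(f"{self.prefix}G{gen}_{k:04d}")
            self.ped_sire.append(int(self.rows[sire_slots[k]]))
            self.ped_dam.append(int(self.rows[dam_slots[k]]))
            self.ped_sex.append(sexes[k])
            self.ped_gen.append(gen)
        return new_haps, np.arange(start, start + n_off)

    def advance(self, gen: int) -> None:
        cfg = self.cfg
        nm, nf = cfg.n_males, cfg.n_females
        rng = self.rng
        if cfg.scheme == "RR":
            sire_slots = rng.integers(0, nm, nm + nf)
            dam_slots = nm + rng.integers(0, nf, nm + nf)
            sexes = ["M"] * nm + ["F"] * nf
            new_fam = self._even_partition()
        elif cfg.scheme == "RF":
            sire_slots = np.empty(nm + nf, dtype=np.intp)
            dam_slots = np.empty(nm + nf, dtype=np.intp)
            # one son per sire family, from a random dam of that family
            for i in range(nm):
                fam_dams = np.flatnonzero(self.fam_of_dam == i)
                sire_slots[i] = i
                dam_slots[i] = nm + rng.choice(fam_dams)
            # one daughter per dam, sired by her family's sire
            for j in range(nf):
                sire_slots[nm + j] = self.fam_of_dam[j]
                dam_slots[nm + j] = nm + j
            sexes = ["M"] * nm + ["F"] * nf
            new_fam = self._even_partition()  # random family-respecting re-fill
        else:  # FR: fixed dam families, rotational sire replacement
            sire_slots = np.empty(nm + nf, dtype=np.intp)
            dam_slots = np.empty(nm + nf, dtype=np.intp)
            for i in range(nm):
                donor = (i - 1) % nm
                fam_dams = np.flatnonzero(self.fam_of_dam == donor)
                sire_slots[i] = donor
                dam_slots[i] = nm + rng.choice(fam_dams)
            for j in range(nf):
                sire_slots[nm + j] = self.fam_of_dam[j]
                dam_slots[nm + j] = nm + j
            sexes = ["M"] * nm + ["F"] * nf
            new_fam = self.fam_of_dam  # families persist
        self.haps, self.rows = self._make_offspring(sire_slots, dam_slots, sexes, gen)
        self.fam_of_dam = new_fam

    def sample_matrix(self, gen: int, label: str | None = None) -> tuple[GenotypeMatrix, dict[str, str]]:
        cfg = self.cfg
        nm = cfg.n_males
        males = self.rng.choice(nm, cfg.sample_males, replace=False)
        females = nm + self.rng.choice(cfg.n_females, cfg.sample_females, replace=False)
        slots = np.concatenate([males, females])
        tag = label or f"{self.prefix}G{gen}"
        names = [f"{tag}_{k:02d}" for k in range(len(slots))]
        sexes = {n: ("M" if i < cfg.sample_males else "F") for i, n in enumerate(names)}
        chrom_labels = np.concatenate(
            [np.full(c.n_snps, c.label, dtype=object) for c in cfg.genome]
        )
        pos = np.concatenate(self.positions)
        ref = np.full(len(pos), "A", dtype=object)
        alt = np.full(len(pos), "G", dtype=object)
        calls = np.concatenate(
            [(h[2 * slots] + h[2 * slots + 1]).astype(np.int8) for h in self.haps],
            axis=1,
        )
        vt = VariantTable(chrom_labels, pos, ref, alt)
        return GenotypeMatrix(names, vt, calls), sexes

    def pedigree(self) -> Pedigree:
        return Pedigree(
            ids=list(self.ped_ids),
            sire=np.array(self.ped_sire),
            dam=np.array(self.ped_dam),
            sex=np.array(self.ped_sex, dtype=object),
            generation=np.array(self.ped_gen),
        )


def simulate_flock(
    cfg: SimConfig,
    positions: list[np.ndarray] | None = None,
    founder_freqs: list[np.ndarray] | None = None,
) -> SimResult:
    """Run the configured flock forward and export sampled generations.

    Deterministic for a fixed ``cfg.seed``. Sampled generations export
    ``sample_males + sample_females`` individuals drawn from the breeding
    population (sires and dams respectively) of that generation.
    ``positions`` optionally fixes the per-chromosome SNP positions (1-based
    bp), e.g. to put independently simulated breeds on a shared panel;
    ``founder_freqs`` fixes the founder allele frequencies, e.g. to model two
    populations drifting apart from a common ancestral pool.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    flock = _Flock(cfg, rng, positions=positions, founder_freqs=founder_freqs)
    samples: dict[int, GenotypeMatrix] = {}
    sample_sex: dict[int, dict[str, str]] = {}
    if 0 in cfg.sample_generations:
        samples[0], sample_sex[0] = flock.sample_matrix(0)
    for gen in range(1, cfg.n_generations + 1):
        flock.advance(gen)
        if gen in cfg.sample_generations:
            samples[gen], sample_sex[gen] = flock.sample_matrix(gen)
    return SimResult(
        config=cfg,
        pedigree=flock.pedigree(),
        samples=samples,
        sample_sex=sample_sex,
        final_haplotypes=flock.haps,
    )


# ---------------------------------------------------------------------------
# study-design fixture: 3 breeds x 3 sampled generations x 30 birds


@dataclass
class StudyFixture:
    genotypes: dict[str, GenotypeMatrix]  # sub-population label -> 30-bird panel
    subpop_map: SubpopulationMap
    plans: dict[str, MatingPlan]
    pedigrees: dict[str, Pedigree]
    joint: GenotypeMatrix  # all 270 birds on the shared panel (per-breed variants differ)


#: (breed, conservation start year, sampling years) of the emulated design.
STUDY_DESIGN: tuple[tuple[str, int, tuple[int, int, int]], ...] = (
    ("BEC", 1998, (2007, 2010, 2015)),
    ("BYC", 1976, (2007, 2010, 2015)),
    ("LSC", 1998, (2010, 2012, 2015)),
)


def generate_study_fixture(
    seed: int,
    genome: list[ChromosomeSpec] | None = None,
    n_males: int = 30,
    n_females: int = 300,
) -> StudyFixture:
    """Three independently founded breeds under the RF scheme, each sampled at
    three generations with 10 males + 20 females (nine 30-bird panels).

    The default genome is desk-scale (5 chromosomes x 1,000 SNPs); marker
    density, not census or scheme, is where this fixture deviates from the
    real survey. Breeds share SNP positions within a replicate so the nine
    panels can be stacked into one joint matrix, but founders are drawn
    independently per breed, which is what creates between-breed
    differentiation. Deterministic for fixed ``seed``.
    """
    genome = genome if genome is not None else default_genome()
    pos_rng = np.random.default_rng(seed)
    shared_positions = [
        np.sort(pos_rng.choice(np.arange(1, c.length_bp + 1), size=c.n_snps, replace=False))
        for c in genome
    ]
    genotypes: dict[str, GenotypeMatrix] = {}
    subpop: dict[str, str] = {}
    sex: dict[str, str] = {}
    plans: dict[str, MatingPlan] = {}
    pedigrees: dict[str, Pedigree] = {}
    blocks: list[GenotypeMatrix] = []
    for b, (breed, start_year, years) in enumerate(STUDY_DESIGN):
        gens = tuple(y - start_year for y in years)
        cfg = SimConfig(
            n_males=n_males,
            n_females=n_females,
            n_generations=max(gens),
            scheme="RF",
            genome=genome,
            sample_generations=gens,
            seed=seed * 7919 + b,  # independent founders per breed
        )
        res = simulate_flock(cfg, positions=shared_positions)
        plans[breed] = MatingPlan(n_males, n_females, start_year)
        pedigrees[breed] = res.pedigree
        for year, gen in zip(years, gens):
            label = f"{breed}{str(year)[-2:]}"
            gm = res.samples[gen]
            names = [f"{label}_{k:02d}" for k in range(gm.n_samples)]
            renamed = GenotypeMatrix(names, gm.variants, gm.calls)
            genotypes[label] = renamed
            for old, new in zip(gm.samples, names):
                subpop[new] = label
                sex[new] = res.sample_sex[gen][old]
            blocks.append(renamed)
    # stack on a shared synthetic panel: same positions across breeds requires
    # identical variant tables; regenerate positions deterministically
    vt = blocks[0].variants
    joint = GenotypeMatrix(
        [s for gm in blocks for s in gm.samples],
        vt,
        np.concatenate([gm.calls for gm in blocks], axis=0),
    )
    return StudyFixture(
        genotypes=genotypes,
        subpop_map=SubpopulationMap(subpop, sex),
        plans=plans,
        pedigrees=pedigrees,
        joint=joint,
    )
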