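"""Per-subpopulation diversity statistics and generational trend summaries.

Covers the four panel statistics reported per breed x generation — observed
and expected heterozygosity, proportion of polymorphic SNPs, and rarefaction
allelic richness — plus sliding-window nucleotide diversity and the
conservation-goal trend flags (retain >= 90% of initial diversity, keep all
inbreeding coefficients below 0.1).

All per-SNP statistics use called genotypes only; SNPs with zero calls in a
sub-population are excluded from that sub-population's averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma
from typing import Mapping, Sequence

import numpy as np

from .io import MISSING, GenotypeMatrix

__all__ = [
    "DiversitySummary",
    "PiWindow",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "proportion_polymorphic",
    "allelic_richness",
    "nucleotide_diversity_windows",
    "diversity_summary",
    "TrendReport",
    "generational_trend",
]


@dataclass
class DiversitySummary:
    """Panel means for one sub-population (one row of the monitoring report)."""

    Ho: float
    He: float
    P_N: float
    A_R: float
    g: int  # standardized gene-copy count used for A_R


def _called_mask(gm: GenotypeMatrix) -> np.ndarray:
    return gm.calls != MISSING


def observed_heterozygosity(gm: GenotypeMatrix) -> float:
    """Mean over SNPs of the fraction of called genotypes that are heterozygous."""
    if gm.n_variants == 0:
        raise ValueError("empty panel")
    called = _called_mask(gm).sum(axis=0)
    het = (gm.calls == 1).sum(axis=0)
    ok = called > 0
    if not ok.any():
        raise ValueError("no SNP has any called genotype")
    return float((het[ok] / called[ok]).mean())


def expected_heterozygosity(gm: GenotypeMatrix, unbiased: bool = False) -> float:
    """Mean over SNPs of He = 2p(1-p), p the ALT frequency among called alleles.

    ``unbiased=True`` applies the small-sample factor 2n/(2n-1) per SNP
    (Nei's unbiased estimator); off by default to match the plain 2pq
    convention of the genotype-toolkit default.
    """
    if gm.n_variants == 0:
        raise ValueError("empty panel")
    n0, n1, n2, _ = gm.genotype_counts()
    called = n0 + n1 + n2
    ok = called > 0
    if not ok.any():
        raise ValueError("no SNP has any called genotype")
    p = (2.0 * n2 + n1)[ok] / (2.0 * called[ok])
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        two_n = 2.0 * called[ok]
        he = he * two_n / (two_n - 1.0)
    return float(he.mean())


def proportion_polymorphic(gm: GenotypeMatrix, panel_size: int | None = None) -> float:
    """Fraction of panel SNPs with both alleles observed in this sub-population.

    ``panel_size`` is the size of the shared QC'd panel (the denominator);
    defaults to the number of SNPs in ``gm`` — pass the joint panel size when
    the sub-population matrix is a subset view.
    """
    n0, n1, n2, _ = gm.genotype_counts()
    called = n0 + n1 + n2
    with np.errstate(invalid="ignore"):
        p = np.where(called > 0, (2.0 * n2 + n1) / (2.0 * called), np.nan)
    segregating = (p > 0.0) & (p < 1.0)
    denom = panel_size if panel_size is not None else gm.n_variants
    if denom <= 0:
        raise ValueError("panel size must be positive")
    return float(segregating.sum() / denom)


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    """log C(n, k) with C(n, k) = 0 for n < k handled by the caller."""
    n = np.asarray(n, dtype=np.float64)
    return np.vectorize(lgamma)(n + 1) - np.vectorize(lgamma)(k + 1) - np.vectorize(lgamma)(n - k + 1)


def allelic_richness(gm: GenotypeMatrix, g: int) -> float:
    """Rarefaction allelic richness at a standardized draw of ``g`` gene copies.

    Per locus: E[number of distinct alleles observed in a subsample of g gene
    copies drawn without replacement] = sum_i (1 - C(N - N_i, g) / C(N, g)),
    with N called copies and N_i copies of allele i; averaged over loci.
    For biallelic loci the result lies in [1, 2]. ``g`` must not exceed the
    called copy count at any included locus.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    n0, n1, n2, _ = gm.genotype_counts()
    called = n0 + n1 + n2
    if not (called > 0).any():
        raise ValueError("no SNP has any called genotype")
    n_copies = 2 * called[called > 0]
    n_alt = (2 * n2 + n1)[called > 0]
    n_ref = n_copies - n_alt
    if (g > n_copies).any():
        j = int(np.argmax(g > n_copies))
        raise ValueError(
            f"g={g} exceeds the {int(n_copies[j])} called gene copies at locus index {j}"
        )

    def expected_present(n_i: np.ndarray) -> np.ndarray:
        # P(allele i absent from the subsample) = C(N - N_i, g) / C(N, g)
        absent = np.zeros(len(n_i))
        feasible = (n_copies - n_i) >= g
        if feasible.any():
            absent[feasible] = np.exp(
                _log_comb(n_copies[feasible] - n_i[feasible], g) - _log_comb(n_copies[feasible], g)
            )
        present = np.where(n_i > 0, 1.0 - absent, 0.0)
        return present

    richness = expected_present(n_ref) + expected_present(n_alt)
    return float(richness.mean())


@dataclass
class PiWindow:
    chromosome: str
    start_bp: int  # 1-based, inclusive
    end_bp: int  # inclusive
    pi: float  # per-bp nucleotide diversity
    n_sites: int


def nucleotide_diversity_windows(
    gm: GenotypeMatrix,
    window_bp: int = 100_000,
    step_bp: int = 10_000,
) -> list[PiWindow]:
    """Sliding-window nucleotide diversity (the 100 kb / 10 kb step preset).

    Per-site pi_s = 2 * c_ref * c_alt / (c * (c - 1)) with c called alleles
    (the mean pairwise difference at the site); window pi sums pi_s over SNPs
    in the window and divides by the nominal window size in bp. Windows are
    anchored at position 1 per chromosome; the final partial window keeps the
    nominal divisor. Sites with fewer than two called alleles are skipped.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window and step must be positive")
    n0, n1, n2, _ = gm.genotype_counts()
    called_copies = 2 * (n0 + n1 + n2)
    alt = 2 * n2 + n1
    ref = called_copies - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(
            called_copies >= 2,
            2.0 * ref * alt / (called_copies * (called_copies - 1.0)),
            0.0,
        )
    vt = gm.variants
    out: list[PiWindow] = []
    for chrom in vt.chromosomes():
        idx = np.flatnonzero(vt.chromosome == chrom)
        pos = vt.position[idx]
        chrom_end = int(pos.max())
        start = 1
        while start <= chrom_end:
            end = start + window_bp - 1
            in_win = (pos >= start) & (pos <= end)
            out.append(
                PiWindow(
                    chromosome=chrom,
                    start_bp=start,
                    end_bp=end,
                    pi=float(pi_site[idx[in_win]].sum() / window_bp),
                    n_sites=int(in_win.sum()),
                )
            )
            start += step_bp
    return out


def diversity_summary(
    gm: GenotypeMatrix,
    g: int | None = None,
    panel_size: int | None = None,
) -> DiversitySummary:
    """All four panel statistics for one sub-population.

    ``g`` (the rarefaction gene-copy count) defaults to the largest value
    supported by the data: the minimum called copy count over loci. It is a
    required, logged parameter of any cross-population comparison — pass the
    same g for every sub-population being compared.
    """
    n0, n1, n2, _ = gm.genotype_counts()
    called = n0 + n1 + n2
    if g is None:
        g = int(2 * called[called > 0].min())
    return DiversitySummary(
        Ho=observed_heterozygosity(gm),
        He=expected_heterozygosity(gm),
        P_N=proportion_polymorphic(gm, panel_size),
        A_R=allelic_richness(gm, g),
        g=g,
    )


@dataclass
class TrendReport:
    """Relative change of each diversity metric against the first generation.

    ``relative_change[metric][label]`` = (x_t - x_first) / x_first, or None
    when the first-generation value is zero (undefined, not a crash).
    """

    generations: list[str]
    relative_change: dict[str, dict[str, float | None]]
    retention_ok: bool
    inbreeding_ok: bool | None
    retention_threshold: float = 0.9
    inbreeding_threshold: float = 0.1


def generational_trend(
    summaries: Mapping[str, DiversitySummary],
    inbreeding: Mapping[str, float] | None = None,
    retention_threshold: float = 0.9,
    inbreeding_threshold: float = 0.1,
) -> TrendReport:
    """Conservation-goal check across ordered generations of one breed.

    ``summaries`` maps generation label -> DiversitySummary, in generation
    order (insertion order is honoured). ``retention_ok`` requires every
    metric in every later generation to retain at least ``retention_threshold``
    of its first-generation value; ``inbreeding_ok`` requires every supplied
    inbreeding coefficient to stay below ``inbreeding_threshold``.
    """
    labels = list(summaries)
    if len(labels) < 2:
        raise ValueError("need at least two generations")
    metrics = ("Ho", "He", "P_N", "A_R")
    first = summaries[labels[0]]
    rel: dict[str, dict[str, float | None]] = {m: {} for m in metrics}
    retention_ok = True
    for lab in labels[1:]:
        cur = summaries[lab]
        for m in metrics:
            x0 = getattr(first, m)
            xt = getattr(cur, m)
            if x0 == 0:
                rel[m][lab] = None
                continue
            change = (xt - x0) / x0
            rel[m][lab] = float(change)
            if xt < retention_threshold * x0:
                retention_ok = False
    inbreeding_ok: bool | None = None
    if inbreeding is not None:
        inbreeding_ok = all(f < inbreeding_threshold for f in inbreeding.values())
    return TrendReport(
        generations=labels,
        relative_change=rel,
        retention_ok=retention_ok,
        inbreeding_ok=inbreeding_ok,
        retention_threshold=retention_threshold,
        inbreeding_threshold=inbreeding_threshold,
    )
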