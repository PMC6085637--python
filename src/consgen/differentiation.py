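"""Between-population structure: FST, Nei distance, NJ tree, genotype PCA.

FST follows the Weir & Cockerham (1984) variance-component estimator for
diploids with the observed-heterozygosity correction; the multi-locus value
is the ratio of summed components sum(a) / sum(a+b+c) (the "weighted" value
of the common command-line tools), with the per-locus mean also reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Sequence

import numpy as np

from .io import MISSING, GenotypeMatrix

__all__ = [
    "FstResult",
    "weir_cockerham_fst",
    "allele_frequencies",
    "nei_distance",
    "nei_distance_matrix",
    "neighbor_joining",
    "genotype_pca",
]


@dataclass
class FstResult:
    """Per-locus WC84 variance components and the multi-locus summaries.

    ``a`` is the among-population component, ``b`` among-individual within
    population, ``c`` within-individual. Loci monomorphic across all
    populations (or without enough calls) carry NaN components and are
    excluded from both summaries. Per-locus FST may be negative; the weighted
    estimate can be slightly negative for undifferentiated populations.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def per_locus_fst(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.a / (self.a + self.b + self.c)

    @property
    def weighted_fst(self) -> float:
        ok = ~np.isnan(self.a)
        denom = (self.a + self.b + self.c)[ok].sum()
        if denom == 0:
            return float("nan")
        return float(self.a[ok].sum() / denom)

    @property
    def mean_fst(self) -> float:
        pl = self.per_locus_fst
        ok = ~np.isnan(pl)
        return float(pl[ok].mean()) if ok.any() else float("nan")


def weir_cockerham_fst(*populations: GenotypeMatrix) -> FstResult:
    """WC84 theta for two or more populations sharing a variant panel.

    Populations must carry the same variants in the same order. Loci need at
    least one called genotype in every population and at least two
    populations with data; loci monomorphic across all populations get NaN
    components.
    """
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    m = populations[0].n_variants
    for pop in populations:
        if pop.n_variants != m:
            raise ValueError("populations must share an identical variant panel")
        if pop.n_samples < 2:
            raise ValueError("each population needs at least 2 individuals")
    r = len(populations)
    n_i = np.zeros((r, m))  # called individuals per pop per locus
    p_i = np.zeros((r, m))  # ALT frequency
    h_i = np.zeros((r, m))  # observed het fraction
    for k, pop in enumerate(populations):
        n0, n1, n2, _ = pop.genotype_counts()
        called = n0 + n1 + n2
        n_i[k] = called
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(called > 0, (2.0 * n2 + n1) / (2.0 * called), np.nan)
            h_i[k] = np.where(called > 0, n1 / called, np.nan)
    valid = (n_i > 0).all(axis=0)
    n_bar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    # monomorphic across all pops, or insufficient data -> excluded
    poly = valid & (p_bar > 0) & (p_bar < 1) | (valid & (s2 > 0))
    a = np.where(poly, a, np.nan)
    b = np.where(poly, b, np.nan)
    c = np.where(poly, c, np.nan)
    return FstResult(a=a, b=b, c=c)


def allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant ALT frequency among called alleles (NaN when uncalled)."""
    return gm.allele_frequencies()


def nei_distance(p1: np.ndarray, p2: np.ndarray) -> float:
    """Nei (1972) standard genetic distance D = -ln I over shared loci.

    ``p1``/``p2`` are ALT-allele frequency vectors over the same loci; each
    biallelic locus contributes both alleles. The identity I accumulates the
    numerator and the two denominators over loci *before* the ratio
    (multi-locus form). Loci with a missing frequency in either population
    are dropped. Returns ``inf`` when I = 0.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    if p1.shape != p2.shape:
        raise ValueError("frequency vectors must align over the same loci")
    ok = ~(np.isnan(p1) | np.isnan(p2))
    if not ok.any():
        raise ValueError("no shared loci with data")
    x, y = p1[ok], p2[ok]
    jxy = (x * y + (1 - x) * (1 - y)).sum()
    jx = (x**2 + (1 - x) ** 2).sum()
    jy = (y**2 + (1 - y) ** 2).sum()
    identity = jxy / np.sqrt(jx * jy)
    if identity <= 0:
        return float("inf")
    return float(-np.log(min(identity, 1.0)))


def nei_distance_matrix(populations: dict[str, GenotypeMatrix]) -> tuple[list[str], np.ndarray]:
    labels = list(populations)
    freqs = {lab: populations[lab].allele_frequencies() for lab in labels}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(freqs[labels[i]], freqs[labels[j]])
    return labels, d


def neighbor_joining(distance_matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Saitou-Nei neighbor joining; returns a newick string with branch lengths.

    Delegates to scikit-bio's NJ implementation (deterministic given input
    order); negative branch lengths are clamped to zero. The matrix must be
    symmetric with a zero diagonal and at least 3 labels.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    d = np.asarray(distance_matrix, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    d = 0.5 * (d + d.T)  # remove float-level asymmetry before strict validation
    np.fill_diagonal(d, 0.0)
    tree = nj(DistanceMatrix(d, ids=list(labels)))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            # move the deficit onto the sibling edge, standard NJ clean-up
            deficit = -node.length
            node.length = 0.0
            for sib in node.siblings():
                if sib.length is not None:
                    sib.length += deficit
                    break
    out = StringIO()
    tree.write(out, format="newick")
    return out.getvalue().strip()


def genotype_pca(
    gm: GenotypeMatrix,
    k: int = 2,
    scale: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the genotype matrix: coordinates and explained-variance fractions.

    Genotype codes are centered per SNP over called genotypes (missing calls
    are mean-imputed, the standard convention); ``scale=True`` divides by
    sqrt(p(1-p)). Zero-variance SNPs are dropped. Sign convention: the
    largest-magnitude loading of each component is made positive. ``k`` above
    the matrix rank is truncated with a warning.
    """
    import warnings

    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = gm.calls.astype(np.float64)
    x[gm.calls == MISSING] = np.nan
    mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mean, inds[1])
    x -= mean
    sd = x.std(axis=0)
    keep = sd > 0
    x = x[:, keep]
    if scale:
        p = mean[keep] / 2.0
        x = x / np.sqrt(np.clip(p * (1 - p), 1e-12, None))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > 1e-10 * s.max()).sum()) if len(s) else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncating", stacklevel=2)
        k = rank
    explained = (s**2) / (s**2).sum()
    coords = u[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            coords[:, j] *= -1.0
    return coords, explained[:k]
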