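"""Pairwise linkage disequilibrium, decay curves, and LD-based effective size.

Two r² estimators are provided. The *composite* estimator is the squared
Pearson correlation of genotype codes (0/1/2) and needs no phase information.
The *EM* estimator obtains maximum-likelihood haplotype frequencies for
unphased diploids (assuming random union of gametes) and computes
r² = D² / (pA·pa·pB·pb). The decay analysis defaults to the EM estimator;
the Ne estimator uses the composite one with the Waples (2006) sampling-bias
correction for the random-mating model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import MISSING, GenotypeMatrix

__all__ = [
    "composite_r2",
    "em_haplotype_r2",
    "genotype_r2_matrix",
    "LdPair",
    "DecayCurve",
    "ld_decay",
    "NeEstimate",
    "ne_from_ld",
    "chromosome_size_class",
]


# ---------------------------------------------------------------------------
# pairwise r²


def composite_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of genotype codes over pairwise-complete calls.

    Returns NaN when either locus is monomorphic among the jointly called
    individuals or fewer than two individuals are called at both loci.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x = a[ok].astype(np.float64)
    y = b[ok].astype(np.float64)
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def genotype_r2_matrix(calls: np.ndarray) -> np.ndarray:
    """All-pairs composite r² for a (samples x loci) call block.

    Missing calls are handled by column-mean imputation for the correlation
    denominator-free case only when no calls are missing; otherwise falls back
    to pairwise-complete loops. Monomorphic columns yield NaN rows/columns.
    """
    calls = np.asarray(calls)
    n, m = calls.shape
    if not (calls == MISSING).any():
        x = calls.astype(np.float64)
        sd = x.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - x.mean(axis=0)) / sd
        r = (z.T @ z) / n
        out = r * r
        out[sd == 0, :] = np.nan
        out[:, sd == 0] = np.nan
        return out
    out = np.full((m, m), np.nan)
    for i in range(m):
        out[i, i] = 1.0
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = composite_r2(calls[:, i], calls[:, j])
    return out


def _em_loglik(n: np.ndarray, pab: float, pa: float, pb: float) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table given haplotype
    frequency pAB and fixed allele frequencies (pa = freq of A-locus ref)."""
    h = np.array(
        [pab, pa - pab, pb - pab, 1.0 - pa - pb + pab]
    )  # AB, Ab, aB, ab
    h = np.clip(h, 0.0, 1.0)
    # genotype probabilities from random union of gametes
    probs = np.zeros((3, 3))
    idx = {(0, 0): 0, (0, 1): 1, (1, 0): 2, (1, 1): 3}  # (a-allele?, b-allele?)
    for (ia, ib), u in idx.items():
        for (ja, jb), v in idx.items():
            probs[ia + ja, ib + jb] += h[u] * h[v]
    mask = n > 0
    if np.any(probs[mask] <= 0):
        return -np.inf
    return float((n[mask] * np.log(probs[mask])).sum())


def em_haplotype_r2(
    a: np.ndarray,
    b: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_starts: int = 3,
    return_freqs: bool = False,
):
    """EM maximum-likelihood r² for two unphased biallelic loci.

    Genotype codes count ALT copies; haplotype 'A' / 'B' here denote the REF
    alleles, but r² is invariant to that labelling. Allele frequencies stay at
    their observed values throughout EM (they are the marginal MLEs); only the
    coupling frequency pAB is iterated, from ``n_starts`` starting points
    (linkage equilibrium and the two boundary extremes), keeping the best
    likelihood. Returns NaN for a monomorphic locus.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    ok = (a != MISSING) & (b != MISSING)
    a = a[ok]
    b = b[ok]
    n_ind = len(a)
    if n_ind < 2:
        return float("nan")
    # 3x3 genotype table, indices = ALT-dosage at each locus
    table = np.zeros((3, 3))
    for ga, gb in zip(a, b):
        table[ga, gb] += 1
    pa = 1.0 - (2 * (a == 2).sum() + (a == 1).sum()) / (2.0 * n_ind)  # freq of REF at locus A
    pb = 1.0 - (2 * (b == 2).sum() + (b == 1).sum()) / (2.0 * n_ind)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    lo = max(0.0, pa + pb - 1.0)
    hi = min(pa, pb)
    starts = [pa * pb, lo + 1e-6 * (hi - lo), hi - 1e-6 * (hi - lo)][:n_starts]
    best = (-np.inf, pa * pb)
    n_dh = table[1, 1]  # double heterozygotes: phase-ambiguous
    for pab in starts:
        pab = min(max(pab, lo + 1e-12), hi - 1e-12) if hi > lo else pa * pb
        for _ in range(max_iter):
            hAB, hAb, haB, hab = pab, pa - pab, pb - pab, 1.0 - pa - pb + pab
            # expected count of AB haplotypes
            n_ab = (
                2 * table[0, 0] + table[0, 1] + table[1, 0]
            )  # unambiguous AB copies (REF dosage = 2 - ALT dosage)
            denom = hAB * hab + hAb * haB
            frac = 0.5 if denom <= 0 else hAB * hab / denom
            new = (n_ab + n_dh * frac) / (2.0 * n_ind)
            new = min(max(new, lo), hi)
            if abs(new - pab) < tol:
                pab = new
                break
            pab = new
        ll = _em_loglik(table, pab, pa, pb)
        if ll > best[0]:
            best = (ll, pab)
    pab = best[1]
    d = pab - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    if return_freqs:
        return float(r2), float(pab), float(pa), float(pb)
    return float(r2)


# ---------------------------------------------------------------------------
# decay curve


@dataclass
class LdPair:
    locus_a: int
    locus_b: int
    distance_bp: int
    r2: float


@dataclass
class DecayCurve:
    """Binned mean r² against inter-SNP distance.

    ``half_decay_distance_bp`` is the distance at which the binned curve first
    drops below half of its maximum bin mean, linearly interpolated between
    bin midpoints; ``None`` when the curve never drops below half-maximum
    within range (reported as "> max distance") or cannot be interpolated.
    """

    bin_edges_bp: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    half_decay_distance_bp: float | None

    @property
    def midpoints_bp(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_bp[:-1] + self.bin_edges_bp[1:])


def _half_decay(mid: np.ndarray, means: np.ndarray) -> float | None:
    ok = ~np.isnan(means)
    if ok.sum() < 2:
        return None
    mid = mid[ok]
    means = means[ok]
    target = means.max() / 2.0
    k = int(np.argmax(means))
    for i in range(k + 1, len(means)):
        if means[i] < target:
            x0, x1 = mid[i - 1], mid[i]
            y0, y1 = means[i - 1], means[i]
            if y0 == y1:
                return float(x1)
            return float(x0 + (y0 - target) / (y0 - y1) * (x1 - x0))
    return None


def ld_decay(
    gm: GenotypeMatrix,
    max_distance_bp: int = 500_000,
    n_bins: int = 5,
    method: Literal["em", "composite"] = "em",
) -> DecayCurve:
    """Bin all intra-chromosomal locus pairs within ``max_distance_bp`` by
    distance and average r² per bin.

    The 5-bin consolidation over 0-500 kb is the survey-parity preset;
    ``n_bins`` is configurable. Pairs where r² is undefined (monomorphic
    locus) are dropped. Empty bins are excluded from the half-decay
    interpolation with a warning.
    """
    if max_distance_bp <= 0 or n_bins < 1:
        raise ValueError("max_distance_bp and n_bins must be positive")
    edges = np.linspace(0, max_distance_bp, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    est = em_haplotype_r2 if method == "em" else composite_r2
    vt = gm.variants
    for chrom in vt.chromosomes():
        idx = np.flatnonzero(vt.chromosome == chrom)
        pos = vt.position[idx]
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                d = pos[jj] - pos[ii]
                if d > max_distance_bp:
                    break
                r2 = est(gm.calls[:, idx[ii]], gm.calls[:, idx[jj]])
                if np.isnan(r2):
                    continue
                b = min(int(d / max_distance_bp * n_bins), n_bins - 1)
                sums[b] += r2
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if (counts == 0).any():
        warnings.warn(
            f"{int((counts == 0).sum())} empty distance bins excluded from half-decay interpolation",
            stacklevel=2,
        )
    mid = 0.5 * (edges[:-1] + edges[1:])
    return DecayCurve(edges, means, counts, _half_decay(mid, means))


# ---------------------------------------------------------------------------
# LD-based effective population size


def chromosome_size_class(label: str) -> str:
    """Chicken chromosome size class: macro (1-5), intermediate (6-10), micro (11+)."""
    digits = "".join(ch for ch in str(label) if ch.isdigit())
    if not digits:
        raise ValueError(f"cannot parse chromosome number from {label!r}")
    k = int(digits)
    if k <= 5:
        return "macro"
    if k <= 10:
        return "intermediate"
    return "micro"


@dataclass
class NeEstimate:
    """Per-chromosome LD-based Ne and size-class averages.

    ``per_chromosome`` holds ``inf`` where the bias-corrected mean r² fell at
    or below the pure-sampling expectation (drift signal indistinguishable
    from noise); such chromosomes are excluded from class averages and counted
    in ``n_infinite``.
    """

    per_chromosome: dict[str, float]
    class_averages: dict[str, float]
    n_infinite: int
    mean_r2_per_chromosome: dict[str, float] = field(default_factory=dict)
    sample_size: float = float("nan")


def _waples_ne(mean_r2: float, s: float) -> float:
    """Invert the Waples (2006) random-mating LD-Ne regression.

    ``s`` is the (harmonic mean) number of genotyped individuals. Uses the
    published large-sample branch for S >= 30 and the small-sample
    coefficients otherwise. Returns ``inf`` when the corrected r² <= 0.
    """
    if s >= 30:
        r2p = mean_r2 - 1.0 / s - 3.19 / (s * s)
        if r2p <= 0:
            return float("inf")
        disc = 1.0 / 9.0 - 2.76 * r2p
        return (1.0 / 3.0 + np.sqrt(max(disc, 0.0))) / (2.0 * r2p)
    r2p = mean_r2 - (0.0018 + 0.907 / s + 4.44 / (s * s))
    if r2p <= 0:
        return float("inf")
    disc = 0.308**2 - 2.08 * r2p
    return (0.308 + np.sqrt(max(disc, 0.0))) / (2.0 * r2p)


def ne_from_ld(gm: GenotypeMatrix, maf_cutoff: float = 0.05) -> NeEstimate:
    """Effective population size from intra-chromosomal composite LD.

    Per chromosome: mean composite r² over all locus pairs passing the MAF
    cutoff, bias-corrected for sample size per Waples (2006), inverted to Ne
    under the random-mating drift expectation. Chromosome estimates are then
    averaged within the macro/intermediate/micro size classes and overall.
    Intra-chromosomal pairing is stated in the output metadata; linked pairs
    bias Ne downward unless the map is long (see methods note).
    """
    if gm.n_samples < 10:
        raise ValueError("need at least 10 individuals for LD-based Ne")
    freq = gm.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= maf_cutoff))
    vt = gm.variants
    per: dict[str, float] = {}
    mean_r2s: dict[str, float] = {}
    n_inf = 0
    s_values: list[float] = []
    for chrom in vt.chromosomes():
        idx = keep[vt.chromosome[keep] == chrom]
        if len(idx) < 2:
            continue
        block = gm.calls[:, idx]
        r2m = genotype_r2_matrix(block)
        iu = np.triu_indices(len(idx), 1)
        vals = r2m[iu]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            continue
        called = (block != MISSING).sum(axis=0).astype(np.float64)
        s = len(called) / (1.0 / called).sum() * 1.0  # harmonic mean sample size
        s_values.append(s)
        mean_r2 = float(vals.mean())
        mean_r2s[chrom] = mean_r2
        ne = _waples_ne(mean_r2, s)
        per[chrom] = ne
        if np.isinf(ne):
            n_inf += 1
    if not per:
        raise ValueError("no chromosome had >= 2 polymorphic loci after the MAF cutoff")
    classes: dict[str, list[float]] = {"macro": [], "intermediate": [], "micro": [], "all": []}
    for chrom, ne in per.items():
        if np.isinf(ne):
            continue
        classes[chromosome_size_class(chrom)].append(ne)
        classes["all"].append(ne)
    class_averages = {
        k: (float(np.mean(v)) if v else float("nan")) for k, v in classes.items()
    }
    return NeEstimate(
        per_chromosome=per,
        class_averages=class_averages,
        n_infinite=n_inf,
        mean_r2_per_chromosome=mean_r2s,
        sample_size=float(np.mean(s_values)) if s_values else float("nan"),
    )
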