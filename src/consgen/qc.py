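"""SNP quality control and LD pruning.

Filters mirror the survey panel's criteria: per-SNP call rate >= 0.95, minor
allele frequency >= 0.05, and a Hardy-Weinberg exact-test p-value above 1e-6.
Exclusion accounting assigns each failing SNP to the *first* criterion it
fails, in the order HWE -> MAF -> call rate, so the per-criterion counts are
exclusive and sum to the total excluded. The per-sample missing-rate
criterion flags (but does not drop) samples above the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import lgamma
from pathlib import Path

import numpy as np

from .io import MISSING, GenotypeMatrix
from .ld import genotype_r2_matrix

__all__ = [
    "QcThresholds",
    "PruneParams",
    "QcReport",
    "hwe_exact_test",
    "apply_qc",
    "ld_prune",
]


@dataclass
class QcThresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_alpha: float = 1e-6
    max_missing_rate: float = 0.01  # per-sample; flags, does not drop

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"threshold {name}={v} outside [0, 1]")


@dataclass
class PruneParams:
    window_snps: int = 50
    step_snps: int = 5
    r2_threshold: float = 0.2

    def validate(self) -> None:
        if self.step_snps > self.window_snps:
            raise ValueError("step must not exceed window")
        if not (0.0 < self.r2_threshold < 1.0):
            raise ValueError("r2_threshold must lie in (0, 1)")


@dataclass
class QcReport:
    n_input: int
    n_retained: int
    excluded: dict[str, int] = field(default_factory=dict)
    flagged_samples: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded.values())

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton/Cutler/Abecasis style).

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (standard, non-mid-p definition). A monomorphic locus has
    a single possible configuration and returns 1.0.
    """
    n_hom_ref, n_het, n_hom_alt = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no observed genotypes at this locus")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # copies of the rarer allele
    if n_rare == 0:
        return 1.0
    # log-probability of h hets conditional on allele counts:
    #   P(h) = n! / (nAA! h! naa!) * 2^h * nrare! ncommon! / (2n)!
    # where nAA = (n_rare - h)/2, naa = n - nAA - h; h has fixed parity.
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    n_aa = (n_rare - hets) // 2
    n_bb = n - n_aa - hets

    def lg(x: np.ndarray) -> np.ndarray:
        return np.vectorize(lgamma)(x + 1.0)

    logp = (
        lg(np.array(n)) - lg(n_aa) - lg(hets) - lg(n_bb)
        + hets * np.log(2.0)
        + lg(np.array(n_rare)) + lg(np.array(2 * n - n_rare)) - lg(np.array(2 * n))
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = np.flatnonzero(hets == n_het)
    if len(obs) == 0:
        raise ValueError("heterozygote count incompatible with allele counts")
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def apply_qc(gm: GenotypeMatrix, thr: QcThresholds = QcThresholds()) -> tuple[GenotypeMatrix, QcReport]:
    """Remove variants failing HWE, MAF, or call-rate criteria.

    Each excluded SNP is counted once, under the first criterion it fails
    (HWE, then MAF, then call rate). Samples whose missing fraction exceeds
    ``thr.max_missing_rate`` are reported in ``flagged_samples`` but kept.
    Running the filter twice equals running it once.
    """
    thr.validate()
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    n0, n1, n2, nmiss = gm.genotype_counts()
    called = n0 + n1 + n2
    n_samples = gm.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, (2.0 * n2 + n1) / (2.0 * called), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    call_rate = called / n_samples

    fail_hwe = np.zeros(gm.n_variants, dtype=bool)
    if thr.hwe_alpha > 0:
        for j in range(gm.n_variants):
            if called[j] == 0:
                continue  # handled by the call-rate criterion
            fail_hwe[j] = hwe_exact_test(n0[j], n1[j], n2[j]) <= thr.hwe_alpha
    fail_maf = np.isnan(maf) | (maf < thr.min_maf)
    fail_call = call_rate < thr.min_call_rate

    reason = np.full(gm.n_variants, "", dtype=object)
    reason[fail_call] = "call_rate"
    reason[fail_maf] = "maf"
    reason[fail_hwe] = "hwe"  # highest precedence last: overwrites
    keep = reason == ""

    excluded = {
        "hwe": int((reason == "hwe").sum()),
        "maf": int((reason == "maf").sum()),
        "call_rate": int((reason == "call_rate").sum()),
    }
    sample_missing = (gm.calls == MISSING).mean(axis=1)
    flagged = [s for s, m in zip(gm.samples, sample_missing) if m > thr.max_missing_rate]
    report = QcReport(
        n_input=gm.n_variants,
        n_retained=int(keep.sum()),
        excluded=excluded,
        flagged_samples=flagged,
    )
    return gm.subset_variants(np.flatnonzero(keep)), report


def ld_prune(gm: GenotypeMatrix, params: PruneParams = PruneParams()) -> np.ndarray:
    """Greedy windowed LD pruning (the 50-SNP / 5-SNP-step / r² > 0.2 recipe).

    Within each window of ``window_snps`` retained SNPs, while any pair
    exceeds the composite-r² threshold, the member of the worst (highest-r²)
    pair with the lower MAF is removed (tie -> the later position). The window
    then advances by ``step_snps``. Returns retained variant indices in
    original order. As in any single-pass greedy windowed scheme, the
    guarantee is that every retained pair within ``window_snps - step_snps``
    panel positions of each other was jointly checked against the threshold.
    """
    params.validate()
    freq = gm.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    vt = gm.variants
    removed = np.zeros(gm.n_variants, dtype=bool)
    for chrom in vt.chromosomes():
        chrom_idx = np.flatnonzero(vt.chromosome == chrom)
        start = 0
        while start < len(chrom_idx):
            active = [j for j in chrom_idx[start:] if not removed[j]][: params.window_snps]
            if len(active) >= 2:
                _prune_window(gm, np.array(active), maf, removed, params.r2_threshold)
            start += params.step_snps
    return np.flatnonzero(~removed)


def _prune_window(
    gm: GenotypeMatrix,
    window: np.ndarray,
    maf: np.ndarray,
    removed: np.ndarray,
    threshold: float,
) -> None:
    r2 = genotype_r2_matrix(gm.calls[:, window])
    np.fill_diagonal(r2, np.nan)
    alive = np.ones(len(window), dtype=bool)
    while True:
        sub = np.where(np.outer(alive, alive), r2, np.nan)
        if np.all(np.isnan(sub)) or np.nanmax(sub) <= threshold:
            break
        i, j = np.unravel_index(np.nanargmax(sub), sub.shape)
        gi, gj = window[i], window[j]
        # drop the lower-MAF member; ties -> the later position
        if maf[gi] < maf[gj]:
            victim = i
        elif maf[gj] < maf[gi]:
            victim = j
        else:
            victim = i if gm.variants.position[gi] > gm.variants.position[gj] else j
        alive[victim] = False
        removed[window[victim]] = True
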