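"""Runs of homozygosity: sliding-window detection, summaries, group tests.

The detector scans each individual's chromosome with a physical-length
window (1 Mb by default) anchored at every SNP. A window is scored
homozygous when it contains at most one heterozygous and at most five
missing calls; a SNP is eligible when at least ``hit_fraction`` of the
windows covering it are homozygous; maximal runs of consecutive eligible
SNPs, split at large inter-SNP gaps, become segments after length, SNP-count
and density filters. Segment boundaries are the first and last SNP positions
of the run (not window edges); a run of homozygosity must span more than
100 kb and contain at least 50 SNPs under the default parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix

__all__ = [
    "RohParams",
    "RohSegment",
    "RohSummary",
    "detect_roh",
    "merge_segments_per_individual",
    "summarize_roh",
    "compare_roh_groups",
    "write_segments_bed",
    "write_segments_tsv",
]


@dataclass
class RohParams:
    window_bp: int = 1_000_000
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    min_length_bp: int = 100_000
    min_snps: int = 50
    hit_fraction: float = 0.05
    max_gap_bp: int = 1_000_000
    max_density_kb_per_snp: float = 50.0

    def validate(self) -> None:
        if min(self.window_bp, self.min_length_bp, self.min_snps, self.max_gap_bp) <= 0:
            raise ValueError("window/length/snp/gap parameters must be positive")
        if not (0.0 < self.hit_fraction <= 1.0):
            raise ValueError("hit_fraction must lie in (0, 1]")
        if self.max_het_per_window < 0 or self.max_missing_per_window < 0:
            raise ValueError("per-window budgets must be non-negative")


@dataclass
class RohSegment:
    sample: str
    chromosome: str
    start_bp: int  # position of the first SNP in the run (1-based)
    end_bp: int  # position of the last SNP (inclusive)
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _eligible_snps(pos: np.ndarray, calls: np.ndarray, p: RohParams) -> np.ndarray:
    """Boolean eligibility per SNP via the anchored-window scan (vectorized)."""
    n = len(pos)
    het = np.cumsum(np.concatenate(([0], calls == 1)))
    mis = np.cumsum(np.concatenate(([0], calls == MISSING)))
    # window anchored at SNP i covers SNPs [i, e_i) with pos < pos[i] + window_bp
    end = np.searchsorted(pos, pos + p.window_bp, side="left")
    homoz = (het[end] - het[np.arange(n)] <= p.max_het_per_window) & (
        mis[end] - mis[np.arange(n)] <= p.max_missing_per_window
    )
    # windows covering SNP j are anchors i in [lo_j, j] with pos[i] > pos[j] - window_bp
    lo = np.searchsorted(pos, pos - p.window_bp, side="right")
    hcum = np.cumsum(np.concatenate(([0], homoz)))
    j = np.arange(n)
    n_cover = j - lo + 1
    n_hit = hcum[j + 1] - hcum[lo]
    return n_hit / n_cover >= p.hit_fraction


def _runs_to_segments(
    sample: str,
    chrom: str,
    pos: np.ndarray,
    eligible: np.ndarray,
    p: RohParams,
) -> list[RohSegment]:
    segs: list[RohSegment] = []
    n = len(pos)
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1] and pos[j + 1] - pos[j] <= p.max_gap_bp:
            j += 1
        length = int(pos[j] - pos[i] + 1)
        n_snps = j - i + 1
        density = (length / 1000.0) / n_snps
        if length >= p.min_length_bp and n_snps >= p.min_snps and density <= p.max_density_kb_per_snp:
            segs.append(RohSegment(sample, chrom, int(pos[i]), int(pos[j]), n_snps))
        i = j + 1
    return segs


def detect_roh(gm: GenotypeMatrix, params: RohParams = RohParams()) -> list[RohSegment]:
    """Detect ROH for every individual in ``gm``.

    Output is deterministic, sorted by (sample order, chromosome order,
    start). Variants must be position-sorted within chromosomes (enforced).
    """
    params.validate()
    gm.variants.validate()
    vt = gm.variants
    out: list[RohSegment] = []
    for si, sample in enumerate(gm.samples):
        for chrom in vt.chromosomes():
            idx = np.flatnonzero(vt.chromosome == chrom)
            pos = vt.position[idx]
            calls = gm.calls[si, idx]
            eligible = _eligible_snps(pos, calls, params)
            out.extend(_runs_to_segments(sample, chrom, pos, eligible, params))
    return out


def merge_segments_per_individual(
    segments: Sequence[RohSegment],
) -> dict[str, list[tuple[int, int]]]:
    """Per-sample (start, end) intervals with book-keeping offsets per chromosome.

    Concatenates chromosomes on a per-sample basis by keeping intervals as-is;
    intervals from different chromosomes never overlap because coordinates are
    paired with chromosome at the caller when needed. Intended as the feeder
    for :func:`consgen.inbreeding.f_roh`, which only needs lengths.
    """
    per: dict[str, list[tuple[int, int]]] = {}
    offset: dict[str, int] = {}
    running = 0
    for seg in segments:
        if seg.chromosome not in offset:
            offset[seg.chromosome] = running
            running += 1_000_000_000  # separate chromosomes on a synthetic axis
        o = offset[seg.chromosome]
        per.setdefault(seg.sample, []).append((seg.start_bp + o, seg.end_bp + o))
    return per


@dataclass
class RohSummary:
    """Distribution (mean/SD/min/max) of the per-individual ROH measures.

    Rows: NSEG (segment count), KB (total kb in segments), KB_AVER (mean
    segment kb), NSNP (mean SNPs per segment), DENSITY (mean kb per SNP
    within segments) and, when genotypes are supplied, PHOM (genome-wide
    fraction of called genotypes that are homozygous).
    """

    per_individual: pd.DataFrame  # index = sample, columns = measures
    table: pd.DataFrame  # index = measure, columns = mean/sd/min/max


def summarize_roh(
    segments: Sequence[RohSegment],
    samples: Sequence[str],
    gm: GenotypeMatrix | None = None,
) -> RohSummary:
    """Per-individual and per-population ROH summary statistics.

    Samples with zero segments contribute zeros. SD is the sample standard
    deviation (ddof=1), NaN for a single individual.
    """
    rows = {}
    by_sample: dict[str, list[RohSegment]] = {s: [] for s in samples}
    for seg in segments:
        if seg.sample not in by_sample:
            raise ValueError(f"segment for unknown sample {seg.sample!r}")
        by_sample[seg.sample].append(seg)
    for s in samples:
        segs = by_sample[s]
        nseg = len(segs)
        kb = sum(seg.length_bp for seg in segs) / 1000.0
        rows[s] = {
            "NSEG": float(nseg),
            "KB": kb,
            "KB_AVER": kb / nseg if nseg else 0.0,
            "NSNP": float(np.mean([seg.n_snps for seg in segs])) if nseg else 0.0,
            "DENSITY": float(np.mean([seg.length_bp / 1000.0 / seg.n_snps for seg in segs])) if nseg else 0.0,
        }
    per = pd.DataFrame.from_dict(rows, orient="index").loc[list(samples)]
    if gm is not None:
        lookup = {s: i for i, s in enumerate(gm.samples)}
        phom = []
        for s in samples:
            calls = gm.calls[lookup[s]]
            called = calls != MISSING
            phom.append(float(((calls == 0) | (calls == 2))[called].sum() / max(called.sum(), 1)))
        per["PHOM"] = phom
    table = pd.DataFrame(
        {
            "mean": per.mean(),
            "sd": per.std(ddof=1),
            "min": per.min(),
            "max": per.max(),
        }
    )
    return RohSummary(per_individual=per, table=table)


def compare_roh_groups(
    values: Sequence[float],
    groups: Sequence[str],
    n_permutations: int = 9_999,
    seed: int = 0,
) -> tuple[float, float, dict[str, int]]:
    """Kruskal-Wallis test of a per-individual ROH measure across groups,
    with a permutation p-value.

    Returns (H statistic, p, per-group n). The p-value is the permutation
    tail probability (1 + #permuted H >= observed) / (n_permutations + 1)
    under random relabelling; constant data yield p = 1.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(groups, dtype=object)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    for g in uniq:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")
    if np.ptp(values) == 0.0:
        return 0.0, 1.0, {str(g): int((labels == g).sum()) for g in uniq}

    def h_stat(lab: np.ndarray) -> float:
        return float(stats.kruskal(*(values[lab == g] for g in uniq)).statistic)

    obs = h_stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    lab = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if h_stat(lab) >= obs - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return obs, float(p), {str(g): int((labels == g).sum()) for g in uniq}


def write_segments_bed(segments: Sequence[RohSegment], path: str | Path) -> None:
    """BED (0-based half-open) with the sample in column 4.

    Internal coordinates are 1-based inclusive; start is shifted down by one
    on output per BED convention.
    """
    with Path(path).open("w") as fh:
        for seg in segments:
            fh.write(f"{seg.chromosome}\t{seg.start_bp - 1}\t{seg.end_bp}\t{seg.sample}\n")


def write_segments_tsv(segments: Sequence[RohSegment], path: str | Path) -> None:
    """PLINK-.hom-style table: sample, chrom, start, end (1-based), n_snps, kb."""
    with Path(path).open("w") as fh:
        fh.write("sample\tchrom\tstart\tend\tn_snps\tkb\n")
        for seg in segments:
            fh.write(
                f"{seg.sample}\t{seg.chromosome}\t{seg.start_bp}\t{seg.end_bp}"
                f"\t{seg.n_snps}\t{seg.length_bp / 1000.0:.3f}\n"
            )
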