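"""Runs of homozygosity and genomic inbreeding in a drifting flock.

Simulates a small flock on a dense SNP map so that autozygous segments are
visible, detects ROH with the 1 Mb sliding-window criteria, and summarizes
segment counts, lengths, and the genomic inbreeding coefficient F_ROH.
"""

import consgen as cg
from consgen.roh import RohParams

genome = [cg.ChromosomeSpec("gga1", 3_000_000, 500, cm_per_mb=3.0)]
cfg = cg.SimConfig(3, 9, 12, "RR", genome=genome, seed=9,
                   sample_generations=(12,), sample_males=3, sample_females=9)
gm = cg.simulate_flock(cfg).samples[12]

params = RohParams(min_snps=25)  # desk-scale map: fewer SNPs per 100 kb than a real panel
segments = cg.detect_roh(gm, params)
summary = cg.summarize_roh(segments, gm.samples, gm)
print("Per-population ROH summary (mean over individuals):")
print(summary.table.round(3).to_string())

merged = cg.merge_segments_per_individual(segments)
for s in gm.samples:
    merged.setdefault(s, [])
froh, per = cg.f_roh(merged, genome_length_bp=3_000_000)
print(f"\nPopulation F_ROH = {froh:.4f} (fraction of the SNP-covered genome in ROH)")
print("Twelve generations at a census of 12 birds produce substantial autozygosity;")
print("a well-managed conservation flock keeps this coefficient below 0.1.")

stat, p, n = cg.compare_roh_groups(
    summary.per_individual["KB"], ["M"] * 3 + ["F"] * 9, n_permutations=999, seed=0
)
print(f"\nKruskal-Wallis (sexes, a null grouping here): H = {stat:.2f}, permutation p = {p:.3f}")
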