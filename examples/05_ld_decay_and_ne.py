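"""LD decay with distance and LD-based effective population size.

In a small closed flock, linkage disequilibrium extends over long distances;
its decay curve summarizes haplotype-block scale, and the mean r² between
effectively unlinked loci estimates the effective population size.
"""

import numpy as np

import consgen as cg

# dense short chromosome for the decay curve
genome = [cg.ChromosomeSpec("gga1", 2_000_000, 300, cm_per_mb=30.0)]
cfg = cg.SimConfig(10, 40, 30, "RR", genome=genome, seed=7,
                   sample_generations=(30,), sample_males=10, sample_females=20)
gm = cg.simulate_flock(cfg).samples[30]

curve = cg.ld_decay(gm, max_distance_bp=500_000, n_bins=10, method="composite")
print("distance bin (kb)   mean r2   pairs")
for k in range(10):
    print(f"{curve.bin_edges_bp[k] / 1e3:6.0f}-{curve.bin_edges_bp[k + 1] / 1e3:<6.0f}"
          f"      {curve.mean_r2[k]:.3f}   {int(curve.n_pairs[k])}")
hd = curve.half_decay_distance_bp
print(f"half-decay distance: {hd / 1e3:.1f} kb" if hd else "half-decay distance: > 500 kb")

# long genetic map (near-unlinked pairs) for the Ne estimate
genome = cg.default_genome(5, 100, length_bp=100_000_000, cm_per_mb=10.0)
cfg = cg.SimConfig(25, 25, 20, "RR", genome=genome, seed=3,
                   sample_generations=(20,), sample_males=25, sample_females=25)
gm = cg.simulate_flock(cfg).samples[20]
est = cg.ne_from_ld(gm)
print("\nper-chromosome LD-Ne:",
      {k: round(float(v), 1) for k, v in est.per_chromosome.items()})
print("class averages:",
      {k: round(float(v), 1) for k, v in est.class_averages.items()})
print("The flock's true census is 50; the corrected LD estimate recovers its")
print("order of magnitude from a single generation of genotypes.")
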