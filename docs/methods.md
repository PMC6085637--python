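# Methods

This note documents the models, estimators, and numerical conventions
implemented in `consgen`, the choices made where conventions genuinely
diverge, and what the simulator does and does not emulate.

## Setting

A conserved flock is a closed population kept at a constant breeding census
of N_m sires and N_f dams with discrete, non-overlapping generations (one
per year in the reference design). Monitoring asks two questions per
sampled generation: how much diversity remains relative to the founding
generation (goal: ≥ 90% retention), and how much inbreeding has accumulated
(goal: all coefficients < 0.1).

## Mating-plan inbreeding (F_ES)

The per-generation increment is taken as

    ΔF = (3·N_f + N_m) / (16·N_m·N_f),  equivalently  Ne = 8·N_m·N_f / (3·N_f + N_m),

and accumulates as F_ES(t) = 1 − (1 − ΔF)^t. Two conventions deserve
explicit notice:

1. **The rate convention.** Classical theory for a two-sex population with
   equalized family sizes gives 1/Ne = 3/(16·N_m) + 1/(16·N_f) and
   ΔF = 1/(2Ne) — *half* the rate above. The doubled rate (ΔF = 1/Ne) is the
   convention under which the published monitoring tables for the three
   reference breeds are reproduced exactly, so `delta_f` adopts it for
   reporting. The halved, textbook rate is what the simulator actually
   realises (see *Simulator validation* below); `f_es` documents this in its
   docstring and the discrepancy is deliberately left visible rather than
   reconciled.
2. **Rounding before accumulation.** `f_es` rounds ΔF to five decimals
   (0.00646 for the 30/300 census) before compounding, because only the
   rounded-rate trajectory matches the published values at all nine sampled
   (breed, year) points at four-decimal reporting precision (the unrounded
   rate differs in the fourth decimal at t = 9 and t = 34). Pass
   `delta_f_decimals=None` for the unrounded rate.

Breed averages are means of the three *rounded* generation values, matching
the published averaging convention.

## Genomic inbreeding (F_ROH)

F_ROH is the fraction of the SNP-covered autosomal genome inside runs of
homozygosity; the denominator is the summed per-chromosome maximum SNP
position. It is deliberately *not* a method-of-moments SNP-by-SNP
coefficient: the genome-fraction definition governs.

ROH detection scans each individual and chromosome with a 1 Mb window
anchored at every SNP. A window is homozygous if it has ≤ 1 heterozygous and
≤ 5 missing calls; a SNP is eligible if ≥ 5% of the windows covering it are
homozygous; maximal runs of eligible SNPs, split at inter-SNP gaps > 1 Mb,
become segments if they span ≥ 100 kb, contain ≥ 50 SNPs, and average
≤ 50 kb per SNP. The window is a physical length (the survey's wording)
rather than a SNP count (the classical tool's parameterisation); boundaries
are the first/last SNP positions of the run, not window edges. The
eligibility fraction, gap, and density defaults follow the classical tool's
conventions since the survey is silent; all are explicit `RohParams` fields
recorded in output headers. The detector is validated against a brute-force
per-definition rescan on randomized ≤ 200-SNP chromosomes.

PHOM (summary tables) is the genome-wide fraction of called genotypes that
are homozygous, not the fraction inside segments — the reading consistent
with reported values near 0.99.

## Diversity statistics

He is plain 2p(1−p) averaged over SNPs (the common genotype-toolkit
default); Nei's small-sample factor 2n/(2n−1) is available behind a flag.
P_N divides segregating SNPs by the shared QC'd panel size, so
sub-populations are compared against one denominator. Allelic richness uses
the hypergeometric rarefaction formula at a standardized gene-copy count g;
g is a required, logged parameter of any comparison (the pipeline uses the
largest value supported by all sub-populations). Windowed π anchors windows
at position 1, steps by 10 kb, and divides by the nominal window size
including the final partial window — the common windowed-π convention.

Per-SNP statistics use called genotypes only; the missing-data conventions
are per-statistic and documented on each function.

## QC

Criteria: HWE exact p > 1e−6 (two-sided Wigginton-style enumeration,
non-mid-p), MAF ≥ 0.05, per-SNP call rate ≥ 0.95. The survey lists both a
call-rate and a missing-rate criterion, which conflict if both are per-SNP;
here call rate is per-SNP and missing rate (≤ 1%) is per-sample, flagging
but not dropping samples, since the reference design retained all
individuals. Exclusion accounting is exclusive and ordered (HWE → MAF →
call rate), echoing the additive category counts of the reference report.
Whether QC was applied jointly or per sub-population is unstated in the
source; the pipeline applies it jointly.

LD pruning is the greedy windowed scheme (50-SNP window, 5-SNP step,
composite r² > 0.2, drop the lower-MAF member of the worst pair, ties to the
later position). Like any single-pass windowed greedy scheme, its guarantee
is that every retained pair within window − step panel positions was jointly
checked.

## Differentiation

FST is the Weir–Cockerham (1984) variance-component estimator for diploids
with the observed-heterozygosity correction; the multi-locus value is
Σa / Σ(a+b+c) ("weighted"), with the per-locus mean also exposed because
reports do not always say which of the two they print. Between-generation
and between-breed comparisons use the same estimator. Nei's (1972) identity
accumulates numerator and denominators across loci before the ratio.
Neighbor joining delegates to scikit-bio's Saitou–Nei implementation behind
the module surface, with negative branch lengths clamped to zero; the
package's own tests verify exact recovery of generating trees from additive
matrices. PCA centers genotype codes per SNP (mean imputation of missing
calls) without variance scaling by default; scaling by √(p(1−p)) is a flag.

## LD and effective population size

Two r² estimators: the composite estimator (squared Pearson correlation of
genotype codes, pairwise-complete) and the EM maximum-likelihood estimator
for unphased diploids. The EM iterates only the coupling frequency p_AB
(allele frequencies are the marginal MLEs and stay fixed), from three
starting points with tolerance 1e−8, keeping the best likelihood; it is
validated against an exhaustive 1-D profile-likelihood grid.

Decay curves bin intra-chromosomal pairs by distance (default five bins over
0–500 kb, the survey-parity preset; bin count configurable) and use the EM
estimator by default. The half-decay distance interpolates linearly between
the bin midpoints bracketing half of the maximum bin mean — a convention of
this package, since the source does not state one; it is `None` ("beyond
range") when the curve never crosses half-maximum.

Ne inverts the random-mating drift expectation from the mean composite r²
over intra-chromosomal pairs, after the Waples (2006) sampling-bias
correction (large-sample branch for S ≥ 30, published small-sample
coefficients otherwise). Chromosomes whose corrected r² falls at or below
zero are flagged infinite and excluded from the macro (gga1–5),
intermediate (gga6–10), micro (gga11–28) and overall class averages.
Intra-chromosomal pairing is stated in output metadata; with short genetic
maps it biases Ne downward (linked pairs carry more LD than the unlinked
model assumes), which is why the recovery experiment below uses long maps.

## Simulator

Founders are drawn in linkage equilibrium with allele frequencies uniform on
[0.05, 0.5] (a post-ascertainment SNP-panel spectrum, not a neutral site
spectrum). Gametes recombine with Poisson crossovers (no interference) at
length_Mb × cM/Mb per chromosome, default 3 cM/Mb — the chicken
macrochromosome order of magnitude. There is no mutation: on horizons of a
few dozen generations drift dominates. Offspring sex is independent at 1/2,
realised by generating sons and daughters directly for their quota slots.
Replacement schemes:

- **R:R** — every breeder slot is filled by an offspring of a uniformly
  drawn sire and dam.
- **R:F** — dams are partitioned evenly among sires into families; exactly
  one son is kept per sire family (from a random dam of that family) and one
  daughter per dam; new dams are re-partitioned among new sires at random.
  The source wording ("random mating within families") is ambiguous; this
  random cross-family pairing is the adopted reading, and the alternative —
  matings confined within families — was rejected because it produces
  half-sib line breeding and inbreeding far above anything reported.
- **F:R** — dam families are fixed; family i's replacement sire is a son
  born in family i−1 (mod N_m).

The fixture generator reproduces the reference design: three independently
founded breeds (shared SNP positions, independent founder frequencies) under
R:F at 30/300, sampled at the published (breed, year) points with 10 males
and 20 females per generation, on a desk-scale panel (default 5 chromosomes
× 1,000 SNPs; the real survey's ~716k-SNP density is the one feature the
fixture does not emulate, which is why marker-density-sensitive quantities
such as ROH counts and half-decay distances are validated by oracle tests
rather than against published numbers).

### Simulator validation

Pedigree inbreeding exploits the discrete-generation structure: the kinship
matrix of generation g is assembled from generation g−1, giving exact
tabular-method coefficients in one dense step per generation.

At the reference census (30/300) over 17 generations and 20 replicates the
simulator gives mean pedigree F ≈ 0.053 under R:F and ≈ 0.071 under R:R —
i.e. 1 − (1 − ΔF/2)^t and 1 − (1 − 1/(2·4N_mN_f/(N_m+N_f)))^t respectively,
matching classical theory, and preserving the ordering F(R:F) < F(R:R) that
motivates family equalization. The published F_ES trajectory (0.104 at
t = 17) runs at twice this rate, as discussed above; the package reports
F_ES by the published convention and validates the simulator against the
theoretical one. He retention under R:F likewise tracks (1 − ΔF/2)^t.

The LD-Ne recovery experiment simulates random-mating flocks of true size
25/50/100 for 20 generations on five 1,000 cM chromosomes (100 Mb at
10 cM/Mb — micro-chromosome-like recombination), 100 SNPs each, sampling
up to 50 individuals. The long maps make the average intra-chromosomal pair
effectively unlinked, as the Waples model assumes; median estimates over 20
replicates are monotone in true size and recover size 50 within a factor of
two. Problem sizes throughout (100-SNP pedigree runs, 500-SNP Ne runs,
desk-scale fixtures) were chosen as the smallest at which the statistical
signal in each experiment is stable across replicates.

## Degenerate inputs and tie-breaks

Monomorphic loci: excluded from FST components and r² (undefined), contribute
1 to allelic richness and 0 to He/π. Zero-variance columns are dropped before
PCA. Constant data give p = 1 in the permutation Kruskal–Wallis test
(statistic 0). The F_ES–F_ROH correlation is reported as undefined (NaN)
when either column has zero variance. LD-prune ties on MAF drop the
later-position SNP. Permutation p-values use (1 + exceedances)/(1 + draws)
with ≥ 9,999 seeded permutations by default.

## Known limitations

- The simulator has no mutation, migration, selection, overlapping
  generations, or genotyping error, and its founder spectrum is a panel
  spectrum; it targets the drift/family-structure behaviour of conserved
  flocks, not sequence realism. Passing tests therefore demonstrate
  correctness of the estimators and the drift-level behaviour of the
  schemes, not concordance with any particular real data set.
- Data-dependent quantities of the reference survey (diversity tables, Ne
  tables, ROH distributions, FST values, decay distances) depend on
  unpublished genotypes and are validated structurally (oracles, orderings,
  recovery experiments), not numerically.
- LD-based Ne with intra-chromosomal pairs on short genetic maps is biased
  low; the package reports the pairing in metadata rather than attempting a
  linkage correction.
- The admixture/model-based clustering stage of a typical monitoring report
  is out of scope (external MCMC tooling); PCA, NJ and FST cover structure.
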