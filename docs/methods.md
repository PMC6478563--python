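# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Pedigrees and meiosis counting

A pedigree is a directed acyclic parent→child graph; founders have no
parents, non-founders have both parents present. The power criterion for
shared-segment analysis is the number of meioses between the analyzed
(genotyped) cases: the number of parent→child transmission edges in the
minimal connecting sub-pedigree. We count it as the minimum, over ancestor
couples from which every case descends, of the size of the union of descent
paths from that couple to each case; on multiply-connected (looped)
pedigrees the minimum over path choices is taken, enumerated exhaustively up
to a combination cap and greedily beyond it. The minimum-tree convention is
a deliberate canonical choice: it makes the count reproducible where several
drawable trees exist. Individuals appearing in several families are treated
independently per family.

## FSIR

FSIR is the plain ratio `O/E`, with `E` the sum of per-person stratum
probabilities from a sex × age-band incidence table (half-open age bands,
cross-sectional rates rather than person-years — the inputs available at
desk scale). Significance is the one-sided Poisson tail
`P(X ≥ O | λ = E)`. The Poisson test is discrete and therefore mildly
conservative at small `E`; the calibration test uses large expected counts
where the discreteness is negligible. Kinship-weighted variants of the
statistic exist; the table output deliberately exposes `O` and `E` so a
weighted statistic could be layered on without touching the pipeline.

## Genotype QC

Marker filters run in a fixed order — missingness (> 5%), Hardy–Weinberg
exact test (`p < 0.001`), non-polymorphic, optional strand-ambiguous (A/T,
C/G) — followed by the sample missingness filter (> 5%); the report counts
drops per filter in that order and is bit-reproducible. The HWE test is the
conditional exact test: given the observed allele counts, the probabilities
of all same-parity heterozygote counts are summed over configurations no
more probable than the observed one (log-gamma arithmetic; the test suite
checks equality with an exact-fraction enumeration to 1e-12). HWE is
computed across all genotyped individuals despite their relatedness,
mirroring array-QC practice for family studies; this is conservative and
documented rather than corrected.

## Sharing runs

With biallelic dosage coding, a case subset shares an allele IBS at a marker
iff not both homozygote classes (0 and 2) are present. A shared segment is
a maximal run of consecutive sharing markers on one chromosome; coordinates
are the bp of the first and last sharing marker and `length = end − start`.
Missing genotypes are compatible with sharing by default (missingness should
not break a true IBD run); a strict `break` policy exists for sensitivity
analysis. Runs tolerate no genotyping error — error-tolerant runs are an
explicit non-goal. The subset scan enumerates every case subset of size ≥ 3
(configurable), refusing politely above a subset cap; sharing is
anti-monotone in the subset, so a superset's runs are always contained in
its subsets' runs (a tested invariant). Autosomes only.

## Gene-drop null and empirical p-values

Founders draw two haplotypes uniformly with replacement from the phased
reference panel — whole-chromosome resampling preserves the panel's LD
exactly, which we prefer to block-wise reconstruction because it needs no
additional modeling assumptions. Transmission is Haldane: crossover count
Poisson in map length, positions uniform on the cM scale, no interference.
The batched null engine draws the same process sparsely (per-chromosome
Poisson crossovers mapped onto inter-marker intervals); the test suite
verifies both samplers against the closed-form recombination fraction
`θ = (1 − e^{−2d})/2`.

Each simulation re-runs the subset scan; the null records, per marker and
per subset size `s`, the maximal bp length of a covering run among subsets
of size ≥ `s` (coverage arrays), plus the list of distinct run events
(subset size, interval) from the first `event_sims` simulations (default
1500) — a subsample that keeps memory flat while the coverage arrays always
use every simulation. The empirical p of an observed segment is
`(c + 1)/(n_sims + 1)` with `c` the number of simulations whose covering run
at the segment's anchor marker, for equal-or-larger subset size, is at least
as long. The anchor is the marker nearest the segment's bp midpoint; null
events use the identical anchor rule, which makes the threshold calibration
self-consistent (the compound statistic "run anchored at its own midpoint"
is not exactly probability-integral-transformed marker-by-marker, but the
identical treatment of observed and null segments cancels the effect — the
false-positive calibration test is the direct check). The `+1` floor
prevents zero p-values from finite simulation.

Simulations are generated in fixed-size chunks with RNG substreams spawned
deterministically from the master seed, so a fixed seed yields bit-identical
results regardless of interruption, checkpoint/resume, or worker count.
Checkpoints persist completed chunks.

## Genome-wide thresholds

For a grid of cutoffs `t`, `E(t)` is the mean number of distinct null
segments per simulated genome with empirical `p ≤ t`; `E(1)` is the mean
total segment count. A log-log linear model is fitted over the
decision-relevant window (`E` between 0.05 and 5, bracketing the targets)
and inverted at 0.5 (significant) and 1.0 (suggestive) expected false
positives per genome per family; the same line extrapolates below the
empirical resolution `1/(n_sims+1)` when needed, with extrapolation warnings
recorded in the diagnostics. The log-linear tail is the minimal assumption
consistent with the observed curves (in-sample relative error is checked at
10%); the fit family is intentionally pluggable. When real data are
analyzed the null contains a small fraction of true positives, biasing
thresholds slightly conservative; this is documented, not corrected.
Thresholds shrink as the number of analyzed cases grows because the subset
scan multiplies the events per genome — matching the pattern in the bundled
family summary table.

## Multi-family combination

Single-family regions are reported at the family's significant threshold;
multi-family regions are bp-intersections of suggestive-or-better segments
from ≥ 2 families (intersection, not union — the reported interval is the
evidence common to all contributors). Combined significance is Fisher's
`−2 Σ ln p` against `χ²(2k)`, which requires independent families: an
individual contributing to two families is kept in exactly one — preferably
a family whose sharing subset does not contain them, otherwise the larger
family — and families whose subset drops below two sharing cases leave the
combination; affected families are flagged for p and threshold
recomputation. The tie-break rule is ours; published practice documents only
a single instance.

## Follow-up

Gene targeting intersects coding and regulatory intervals with regions and
then removes blacklisted (false-positive-prone) genes. The literature
enrichment compares the hit proportion among targeted genes with the genome
background by a one-sided two-proportion z without continuity correction;
the headline arithmetic (18/207 = 8.7% observed vs ~4% background, ~8
expected) is the stable quantity — no standard proportion test we
enumerated reproduces the originally printed Z exactly, so the z-formula is
exposed in config and not treated as ground truth. The familial screen
reports rare (reference MAF < 10%) non-synonymous variants strictly inside a
region carried by every case of the sharing subset. The association screen
selects coding, non-synonymous, damaging-by-either-predictor (OR over
non-NA SIFT/PolyPhen calls) variants with reference MAF < 20%, builds the
2×2 minor/major chromosome table against the reference population, and uses
Pearson chi-square without Yates correction when both groups have more than
10 minor-allele chromosomes, else the two-sided (minimum-likelihood)
Fisher's exact test — sidedness and the both-groups reading of the
chromosome rule are documented choices. Cases responsible for the original
sharing evidence are excluded from the case counts before testing.
Significance is Bonferroni at `α/m` (0.05/352 = 1.42e-4 in the worked
example).

## Synthetic data

The generator's defaults emulate the study conditions at desk scale:

- **Pedigrees.** Seven generations from one founder couple, sibship sizes
  Poisson(2.0) clipped to [1, 6], married-in founder spouses, case status
  only in the deepest generation (status is unobservable in upper
  generations of real genealogies), case rate 0.065. These values were
  calibrated once so that 100 generated families average within ±20% of the
  published family scale (6.2 genotyped cases, 29.6 meioses) and then
  frozen.
- **Panel.** 200 haplotypes built by block-pool concatenation: 5-marker
  blocks, 8 pool haplotypes per block, allele frequencies uniform on
  [0.25, 0.75] — strong within-block and weak between-block LD. This is a
  deliberate moderate-LD regime; it exercises run-length statistics and
  founder resampling but is not a coalescent model and has no allele
  frequency spectrum, no recombination hotspots, and uniform marker spacing
  (10 markers/cM, ~10 kb/marker).
- **Planted segments** are forced by overriding the transmission choice
  inside the planted interval along the minimal founder-to-carrier descent
  paths (tractable and exact, at the price of a transmission discontinuity
  at the interval boundary, which does not affect within-interval sharing).
- **Annotations** mirror the published frequency regime for planted
  associated variants (reference frequency 7e-5 vs case frequency 9e-3 in a
  ~1300-case, 2600-chromosome cohort) and plant an explanatory variant on
  the carried founder haplotype.
- **Incidence rates** are plausible cumulative sex × age-band suicide
  incidences with a male excess; they are stand-ins for statewide tables.

Passing tests on these bundles therefore demonstrate internal correctness
and calibration of the machinery, not performance on real array data, whose
LD structure, allele spectrum, genotyping error and ascertainment are all
richer.

## Validation experiments and problem sizes

`sgskit.experiments` fixes the three end-to-end experiments used by the
test suite and the reproduction script, with these problem sizes chosen as
the package's desk-scale defaults:

- *Null calibration*: one 3-case family, 4,000 gene-drop simulations, 400
  fresh null genomes; expected ≈ 0.5 significant and ≈ 1.0 suggestive calls
  per genome (3 SE tolerance).
- *Planted recovery*: 50 replicates, each a fresh 7-case family meeting the
  ≥ 15-meioses criterion with a 3 cM segment planted in 5 cases, 10,000
  simulations each, on a 2-chromosome genome of 200 markers/chromosome at
  ~13 markers/cM; success is a covering segment at the suggestive level
  (≥ 90% expected).
- *Haldane check*: 100,000 simulated meioses across a 10 cM interval.

The gene-drop default `n_sims` is 10,000 at desk scale; the published
protocol's 500,000 is reachable through configuration (`n_sims`), with
checkpointing for long runs.

## Known limitations

- IBD is inferred from IBS runs only; no probabilistic IBD model (HMM) and
  no phased-haplotype sharing.
- No genotyping-error tolerance inside runs; a single miscall breaks a run.
- Thresholds assume the log-linear tail of the exceedance curve; families
  with very few events per genome trigger the fit-degeneracy error rather
  than silently extrapolating.
- The X chromosome is out of scope; sex-specific genetic maps and crossover
  interference are not modeled.
- The kinship-weighted FSIR variant is not implemented; a minority of
  published family rows reflect that weighted statistic and are not
  reproduced by plain O/E.
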