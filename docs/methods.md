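# Methods

`ailqtl` implements the computational stages of a two-strain advanced
intercross line (AIL) study of quantitative and binary atrial septal traits:
cohort simulation, interval mapping, QTL summarization, variant-density
segmentation, candidate filtering, network permutation testing, and
feature-enrichment testing. This note records the models, the parameters
that matter, and the numerical and design choices.

## Breeding design and meiosis model

The simulated pedigree mirrors a closed AIL colony: `n_pairs` breeding pairs
(default 48) housed in a ring of cages, intercrossed from F2 to a terminal
generation `t_final` (default 14). From F3 onward the *cascade* scheme mates
the female of cage *i* with the male of cage *i+1* (wrapping at the last
cage), and every pair contributes exactly one male and one female to the next
generation, which doubles the effective population size relative to random
family sizes. The terminal generation may be expanded to an arbitrary cohort
size (`n_final`), reflecting that the phenotyped generation of such a study
is much larger than the breeding nucleus.

Meiosis uses the Haldane model: crossovers form a Poisson process along the
chromosome (no interference), so transmission along the ordered marker
skeleton is Markov with per-interval switch probability
`r = (1 − exp(−2d/100))/2` for a gap of `d` cM. Founders are two fully
inbred, fully informative strains; genotypes are coded by the count of
`Q`-strain alleles.

## Map expansion

Under random mating, linkage disequilibrium between founder alleles decays
by `(1 − r)` per generation, giving the expected recombinant fraction at
generation `t`

    R_t = 1/2 · [1 − (1 − 2r)(1 − r)^(t−2)],

with `R_2 = r` and a small-`r` growth of roughly `r·t/2` — the map expansion
that motivates AIL fine mapping. The simulator validates this closed form:
with random-mating pedigrees of ≥ 10⁵ transmitted chromosomes, observed
recombinant fractions agree with `R_t` at `t ∈ {2, 6, 10, 14}` within
Monte-Carlo error.

Two genuine finite-population effects are worth recording, because they are
properties of the design rather than of the code:

* **The cascade ring under-expands the map.** Mates drawn from adjacent
  cages are related, so a recombination event frequently re-joins identical
  haplotypes and no new recombinant appears. Even at very large `n_pairs`
  the ring realizes systematically fewer recombinants than `R_t` (about
  60% of the predicted excess at `t = 14` for a 48-pair colony, where drift
  adds further losses). `AILDesign(mating="random")` provides the idealized
  design the closed form describes; `mating="cascade"` (default) is the
  study design.
* **Unlinked loci are not independent at F14.** Drift in a 96-animal colony
  builds cross-chromosome associations, so a marker on another chromosome is
  not an exactly irrelevant covariate in an F14 scan (it is in an F2).

## Trait model

A quantitative trait is `mean + Σ(a·x + d·z) + covariate effects + ε`,
with `x = (#Q alleles) − 1`, `z = 1` for heterozygotes, and
`ε ~ N(0, residual_sd²)`. QTL positions snap to the nearest simulated
marker on their declared chromosome. The binary trait (patent foramen
ovale analogue) uses a liability threshold: the same linear model generates
an unobserved liability and the trait is `liability > threshold`; a
threshold of `Φ⁻¹(1 − 0.34)` reproduces the 34% F14 prevalence of the
motivating study. Sample selection mimics selective genotyping: per-trait
tails plus random fill to the target total, balanced over sex and cage as
far as integer counts allow (tie-breaks are deterministic by row order; the
per-trait extreme counts are parameters).

## Interval mapping

Scans walk a grid (default step 0.25 cM, snapped to include every typed
marker) over each chromosome. Conditional genotype probabilities at a scan
position are the classical flanking-marker conditionals with each interval's
recombination fraction expanded to `R_t`; the two transmitted chromosomes
are treated as independent Markov "AIL gametes". Each individual conditions
on its nearest *informative* flanks, so missing calls fall through to the
next marker, and an individual with no informative marker on the chromosome
receives the 1:2:1 population prior. At `t = 2` this machinery is exactly
the standard F2 interval mapping.

**Quantitative model.** At each position the trait follows a three-component
Gaussian mixture (means `μ_QQ, μ_Qq, μ_qq`, common σ) with per-individual
prior weights from the conditional probabilities; the null is a single
Gaussian. `LOD = log₁₀(L₁/L₀)`, floored at 0. The mixture is maximized by
EM to a relative log-likelihood tolerance of 1e-8 (at most 200 iterations;
non-convergent positions are flagged and keep the best value). Because the
mixture surface is multimodal on small samples, the EM is multi-start: a
Haley–Knott regression start (which begins at or above the nested null), a
quantile start, a few wide random restarts (fixed internal seed, so scans
are deterministic), and — on samples of ≤ 60 with few genotype-ambiguous
individuals — one start per hard assignment of the ambiguous individuals,
which makes the search effectively exhaustive there. σ is floored at 1e-8
to avoid degenerate spikes. A Haley–Knott regression on expected dosage is
retained internally as the initializer and cross-check.

**Binary model.** Logistic regression of the trait on expected additive
dosage and heterozygote probability (hard-call covariates available as an
option), against the null without the position terms;
`LOD = (dev₀ − dev₁)/(2 ln 10)`. Complete separation is detected by a
near-zero residual deviance or a diverging linear predictor; the deviance
improvement is then capped at the saturated-model bound and the position
flagged. No correction is applied for selective genotyping (a documented
limitation; the original analysis is not known to have corrected either).

**Peaks.** Peaks are plateau-collapsed local maxima with LOD at or above
the threshold (default 2.0 for dense AIL panels; 4.3/2.8 are the classical
genome-wide F2 thresholds, kept as constants). The support interval is the
maximal contiguous run with `LOD ≥ peak − 1` (1-LOD drop-off); peaks with
overlapping intervals are flagged. Linked-peak resolution re-scans with the
typed marker nearest the higher peak (ties toward the lower coordinate;
the marker must lie inside the higher peak's support interval) entering
*both* null and alternative models as additive + dominance covariates, so
the likelihood ratio isolates the test position; the verdict is "distinct"
iff the conditional LOD within the lower peak's interval stays at or above
the threshold.

**Effects.** At a position, genotype means are probability-weighted;
`a = (mean_QQ − mean_qq)/2`, `d = mean_Qq − midpoint`, and with parental
means supplied the additive effect is expressed as a percentage of the
parental gap. A QTL is labelled "normal" when its additive effect acts in
the direction of the parental difference and "cryptic" otherwise.

**A caveat on realized support intervals.** The theoretical prediction that
AIL intervals are `t/2`-fold narrower than F2 intervals describes the decay
rate of the *expected* LOD curve. Realized 1-LOD drop-off intervals behave
differently: the realized peak is noise-sharpened (the maximum over
positions sits above the expected curve), which truncates wide F2 intervals
well below their expected-curve crossing, while AIL intervals floor near the
marker spacing. Across matched simulations (same n = 400, same marker
density, moderate effect) the median width ratio is ≈ 3.5, not 7 — in line
with the realized narrowings such studies report. The replicated study
`ci_shrinkage_study` (60 replicate pairs by default, idealized random-mating
design, 0.5 cM panel option) measures this factor; the package reports what
it measures.

## Variant density and candidates

High-quality strain-discriminating variants require depth ≥ 8, estimated
FDR ≤ 10% (ingested as a per-variant field; caller error models are out of
scope), and homozygous-alternate in exactly one strain with reference or
heterozygous in the other. The genome is tiled per chromosome from
position 0 (terminal partial bins keep their true width); the bin-size
sweep (50 kb–1.1 Mb) reports a bimodality diagnostic — the normalized depth
of the antimode between the two largest modes of the lightly smoothed
per-bin count histogram on a square-root scale. Bins with count ≥ cutoff
(default 1000 per 600 kb, inclusive) form high-density segments after
merging adjacent high bins. QTL support intervals are converted from cM to
bp by piecewise-linear interpolation on a marker physical-position table;
intervals are 0-based half-open internally, 1-based at VCF-style
boundaries. Candidate variants lie in QTL intervals, in expressed genes
(CPM > 1, strictly, in ≥ 2 samples), with effect class among high-impact /
deleterious-missense / non-frameshift-deletion; all filters are row-wise
predicates, hence order-independent.

## Network permutation and hub tests

The gene network keeps edges with combined score strictly above 700
(deduplicated symmetric, self-loops dropped). Subnetwork statistics are the
induced edge count and the mean local clustering coefficient over the set's
nodes (degree < 2 contributes 0 — a stated interpretation, as the source
convention is not defined). The permutation null redraws gene sets of the
same size uniformly without replacement from the expressed-gene background
(a per-run input, never a global constant); the empirical p is `k/N` with
`k` the count of permutations reaching the observed statistic, reported as
"< 1/N" when `k = 0`; the conservative `(k+1)/(N+1)` form is an option.
Betweenness centrality is fraction-weighted (networkx); stress centrality
counts raw shortest paths through a node and is computed from all-pairs
BFS distances and path counts (no installed library provides it).
Hub-connection and kinase-substrate tests are one-sided Fisher exact tests
on 2×2 tables of set membership × hub connection, with Benjamini–Hochberg
adjustment across hubs; degenerate margins yield p = 1 with a flag.

## Feature enrichment

Promoters are `[TSS−1000, TSS+100)` on the coding strand (mirrored on the
minus strand, clipped at chromosome bounds). Candidate enhancers are
H3K4me1⁺ and/or H3K27ac⁺ intervals not overlapping H3K4me3⁺, within a
window (50–250 kb, parameterized) of a gene-set TSS. Normalized enrichment
divides the proportion of QTL variants overlapping the feature by the
proportion of QTL length the feature covers. The shuffle null re-places
intervals length-matched to the observed feature∩QTL pieces (longest
first), uniformly at random in the QTL regions minus an exclusion set,
choosing gaps with probability proportional to the number of valid start
positions and avoiding overlap among placed intervals; infeasible placement
raises after bounded retries, naming the offending length. The comparison
statistic is the raw overlap count (not the normalized enrichment); by
default only the complementary gene-set regions are excluded from the
placement pool. Calibration: when the observed feature is itself a draw
from the placement distribution and variants are uniform, the empirical p
is uniform (KS check in the test suite).

## Pipeline and reproducibility

All stage parameters default to the study's operating values (0.25 cM step,
LOD 2, 600 kb bins, cutoff 1000, score 700, 100,000 network permutations,
1000 shuffles, CPM rule). Every stochastic stage derives its seed from the
global seed and the stage name via SHA-256 (seeds stay below 2³¹), so
pipeline runs with the same configuration are byte-identical; floats are
serialized at six significant digits to keep outputs diff-able.

## Replicated study sizes

The replicated simulation studies use 60 matched replicate pairs
(CI shrinkage), 80 replicates at n = 400 and a = 1 residual SD (effect
recovery and interval coverage), and 150–200 calibration runs at reduced
permutation counts (N = 99 permutations / 49 shuffles). These sizes give
Monte-Carlo error well inside the asserted tolerances while keeping the
default suite quick.

## What the generator does and does not emulate

It emulates: the cascade pedigree and its drift, Haldane meiosis,
additive/dominance trait architecture with covariates, liability-threshold
binary traits, selective genotyping with random fill, blocky variant
density from divergent founder haplotypes, stochastic-block-model networks
with a planted dense community, and expression counts with a known
expressed set. It does not emulate mutation, genotyping error, crossover
interference, X-linked inheritance, selection during breeding, realistic
LD beyond the pedigree, or the correlation structure of real expression
data — so passing tests demonstrate correctness of the estimators under
the stated models, not robustness to real-data artifacts.
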