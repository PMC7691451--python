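# Methods

## The question the simulator addresses

Closed companion-animal populations (dog breeds are the motivating case) are
usually managed pairwise: individual breeders pick a mate for one animal at a
time, often guided by a small microsatellite panel, a shallow pedigree, or —
increasingly — genome-wide genotypes. `matesim` is an individual-based
forward simulator built to measure what forty generations of such pairwise
decisions do to *genome-wide* diversity (observed heterozygosity, allelic
richness, coefficient of inbreeding) relative to choosing mates at random.

## Genome model

The genome is a grid of 38 chromosomes x 120 non-recombining 0.5-Mb
haplotype blocks (2.28 Gb), each block a single multi-allelic locus whose
integer allele ids act as haplotype identities. Recombination is uniform:
probability 0.5 across chromosome boundaries and `0.5 Mb x 1e-8 = 0.005`
between adjacent blocks (about 1 cM/Mb, the canine genome-wide average; no
attempt is made to model real chromosome lengths or local rate variation).
A 33-locus multi-allelic marker panel is embedded with a fixed chromosome
distribution (3 on chr 1, 2 each on chrs 2-7, 1 each on chrs 8-25, none on
chrs 26-38), matching the shape of commercial diversity panels. Only per-chromosome
counts are prescribed, so within a chromosome the markers are placed evenly,
at blocks `floor(B*(k+0.5)/m)`; each marker is an extra
locus co-located with its host block and recombines at probability zero with
it, so panel and genome share one genetic map. Loci on chromosomes 26-38 are
reported as an explicit "unlinked" category in distance-stratified outputs
rather than given a large numeric distance.

## Demography and life cycle

A replicate runs founders -> 200 Wright-Fisher generations of burn-in ->
a 5-generation bottleneck at size 50 -> one Wright-Fisher expansion
generation up to N = 200 -> 40 mate-choice generations at N = 200.
Founders carry `k` alleles per locus (default 25 for blocks and markers
alike) distributed round-robin across the `2n` founder gene copies, so
founding frequencies are uniform to within one copy. There is no mutation,
selection, sex, or age structure: diversity can only be lost, which is the
regime of interest.

Burn-in length and the bottleneck are fixed design features; burn-in *size*
controls how much founding diversity survives to the start of mate choice.
The package default, `burn_in_size = 500`, is calibrated so the
pre-mate-choice population looks like a modern heavily-bred dog population:
mean coefficient of inbreeding ~0.25 and mean internal relatedness ~+0.02 at
the start of mate choice, at the conservative end of the 0.2-0.4 block-level
COI span typical of established breeds. Smaller burn-in sizes (100, 200)
give substantially more eroded starting populations (COI ~0.65 and ~0.44)
and remain available. All schedule fields are configurable per
`ParameterSet`.

During mate choice each offspring event (i) samples a first parent uniformly
among individuals that have mated fewer than `maximum_number_of_matings`
times this generation (default: the population size, i.e. unconstrained);
(ii) samples a fresh mating pool of `mating_pool_size` (default 50) others
uniformly without replacement, resampling from scratch until the pool
contains an eligible candidate; (iii) scores the eligible pool under the
active model and takes the best, breaking ties uniformly. Both parents'
counters increment per event — the cap reads strictly, bounding any
individual's total parental contributions. One offspring per event; litters
are not modelled. If no eligible first parent or mate exists the generation
deadlocks and the error reports the generation and eligibility counts
rather than silently relaxing a constraint.

## Mate-choice statistics

All pair statistics enumerate the four ordered gametic pairs (one haplotype
from each prospective parent), which yields exact offspring expectations
without sampling:

* **Expected offspring heterozygosity** (`MS33_HET` over the panel,
  `GW_HET` over all loci): one minus the mean allele-identity of the four
  gametic pairs; maximised.
* **Internal relatedness** (`MS33_IR`): the single-locus IR (1 for an
  identical pair, `-(f_a+f_b)/(2-f_a-f_b)` otherwise) averaged over the four
  gametic pairs and then across loci, as the mate-ranking statistic is
  described; the classical multi-locus ratio-of-sums form is available as an
  option for comparison. Minimised. Note IR rewards *common* alleles in a
  candidate, which is what moderates its popular-parent behaviour.
* **Wang (2002) relatedness** (`MS33_AGR`): a moment estimator for small
  multi-allelic panels. At each locus the probabilities of the three
  informative genotype-similarity categories are linear in the pair's IBD
  coefficients (phi, delta) with frequency-dependent coefficients; the
  estimator solves the overdetermined system by generalised least squares
  under the multinomial covariance of the category indicators at
  unrelatedness and reports `r = phi/2 + delta`. Loci are combined with
  weights proportional to `1/(2*a2 - a3)` applied to both the observed
  category indicators and the mixing coefficients, which keeps the
  estimator exactly unbiased at the reference frequencies (verified by
  Monte Carlo: unrelated pairs score 0, full sibs 0.5). Reference
  frequencies are the full current adult population, recomputed once per
  generation; loci monomorphic in the reference are uninformative and
  excluded. Minimised.
* **Whole-genome relatedness** (`GW_REL`): `2*fbar/sqrt((1+F1)(1+F2))`
  where `fbar` is the mean gametic-pair allele identity and `F_i` the
  individual homozygous fractions (the Hedrick & Lacy normalisation for
  inbred individuals); the unnormalised `2*fbar` is available behind a
  flag. Minimised.
* **Pedigree relatedness** (`PEDIGREE`): Wright path counting over the
  tracked parents and grandparents, excluding path pairs that reuse an
  intermediate individual; untracked ancestors count as unrelated and
  non-inbred. Minimised.
* **Layered choice** (`MS33_IR_AGR`): the best
  `ceil(proportion * pool)` candidates by IR (default proportion 0.5,
  ceiling so the subset is never empty), then the Wang minimum among them.

A scalar reference implementation of every statistic exists alongside a
vectorised scoring path used inside the generation loop; the two are
property-tested for exact agreement, and a brute-force oracle transcription
(independent loops and explicit matrix algebra in the fixtures module) pins
each statistic to 1e-12 on hand-built populations.

## Reporting statistics

Snapshots are taken at mate-choice generation 0, every 5 generations, and at
the end: mean observed heterozygosity over blocks (genome-wide) and over the
panel, mean allelic richness (and a >=5%-frequency variant), mean COI
(`1 - het` at block level, equivalent to the length-weighted definition
because blocks are equal-sized), and mean individual IR. Per-locus richness
is stored at the endpoints by default ("all" and "none" available) to bound
output size while supporting the distance-to-marker analysis.

Effect sizes are reported as mean differences with bias-corrected and
accelerated (BCa) bootstrap 95% intervals (5,000 resamples by default; z0
from the bootstrap distribution, acceleration from the leave-one-out
jackknife), not p-values. Percent losses are computed per replicate relative
to generation 0 of mate choice and compared across replicates. Per-locus
distance profiles resample at the replicate level (the same resample across
loci) so spatial correlation along chromosomes is respected. Degenerate
all-identical inputs return a zero-width interval at the point estimate.

## The reduced-scale comparison study

The directional tests and the acceptance script run one shared study: 20
replicates of the default parameter set, with the burn-in/bottleneck/
expansion history computed once per replicate and shared by every model cell
(RANDOM, MS33-HET, MS33-IR, MS33-AGR, GW-HET, GW-REL, plus MS33-HET and
MS33-AGR rerun with the mating cap tightened to 5). Sharing the
pre-mate-choice history pairs the contrasts, so model-vs-random comparisons
use a one-sample BCa interval on the paired per-replicate differences; this
is both the correct inference for the design and ~6x cheaper than
independent burn-ins. `run_experiment` retains fully independent replicates
for grid-style use. Problem sizes (20 replicates, N = 200, 40 generations,
full 4,593-locus genome) are the package's reduced-scale defaults; grid
runs with more replicates and parameter variants go through
`run_experiment`.

Seeds derive deterministically as
`SeedSequence((base_seed, cell_index, replicate)) -> uint32 % 2**31`, so any
cell is reproducible in isolation and results are independent of worker
count.

## What the synthetic data do and do not show

The simulator is its own data generator; founding diversity, drift, linkage
and the mate-choice feedback are all mechanistic. It does not emulate real
canine chromosome lengths, locus-specific recombination, mutation, selection
or purging, sex/age structure, litters, or population subdivision, so
passing tests demonstrate the comparative behaviour of mate-choice rules
under drift with linkage — not absolute diversity forecasts for any real
breed. The demographic defaults are calibrated stand-ins rather than a fit
to any particular breed's history, so the package's checks are directional
(sign and ordering of effects, closed-form drift rates, estimator
unbiasedness) rather than predictions of absolute diversity levels.

## Numerical choices and degenerate inputs

Allele ids live in the smallest unsigned integer dtype that fits the founder
allele count (uint8 at the defaults), which roughly halves the cost of the
equality comparisons that dominate genome-wide scoring. Gamete formation
draws one uniform per inter-locus interval (float32) and converts switch
indicators to a source-haplotype parity by cumulative sum. Score ties are
detected by exact equality — identical genotype configurations produce
bit-identical scores — and broken by the replicate's generator. A mating
pool larger than the remaining population truncates to "everyone else".
Monomorphic populations are legal everywhere except the Wang estimator,
which raises once every locus is uninformative.

## Known limitations

* Pedigree relatedness is truncated at grandparents (as tracked), so it
  underestimates relatedness accumulated deeper in the pedigree.
* The Wang estimator is implemented from its moment equations and checked
  against an independent transcription and Monte-Carlo unbiasedness, not
  against the original R implementation, which is not redistributable here.
* The bottleneck-to-N expansion is a single unconstrained Wright-Fisher
  generation; real breed expansions take several generations.
* With 20 replicates the smallest contrasts (e.g. GW-REL's richness
  advantage) sit near the resolution limit of the paired design.
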