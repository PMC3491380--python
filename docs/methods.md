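# Methods

`macseq` re-implements, as a self-contained and testable pipeline, the
analysis of a single diploid macaque genome resequenced against the
reference assembly of a closely related species: diploid genotype
calling with assembly-quality-aware filtering, variant-effect
annotation, multi-genome comparison, population-genetic summaries,
mate-pair structural-variant detection, and SMC-HMM demographic
inference. Because the original ~100-Gb read data cannot be processed
at desk scale, the package ships a synthetic-data engine that generates
genomes with the same statistical structure and known ground truth; all
recovery claims in the test suite refer to that engine, not to real
sequencing data.

## The synthetic-data engine

**Reference assembly.** Chromosomes are i.i.d. uniform ACGT with
assembly gaps (N runs; Poisson-placed, exponential lengths) and a
repeat mask. The per-base assembly quality (QV) track is blockwise:
geometric blocks (mean 200 bp) are QV 60 with probability 0.94 —
matching the fraction of the real draft assembly at QV 60 — and
otherwise uniform on 20–59. Blocks, not i.i.d. bases, because draft
assembly quality is locally correlated and the discovery-rate profile
stratifies sites by QV.

**Coalescent tracts.** The two haplotypes of the sample coalesce at a
tract-specific TMRCA generated by a sequential walk: a tract with TMRCA
*T* ends after an Exp(2ρT) distance (recombination anywhere on the two
branches of total length 2*T*), after which the TMRCA is resampled in
full. The resampling density is the *length-biased* coalescent density
∝ t·f(t), where f is the plain coalescent density under the
piecewise-constant history N(t). This is the stationary choice: with a
breakpoint rate proportional to t, only length-biased resampling makes
the per-site TMRCA marginal equal f, so genome heterozygosity obeys
π = 4Nμ and the genome-average TMRCA equals 2N for constant N. (Full
resampling itself is the plain-SMC simplification — real SMC resamples
conditionally on the standing time — and is documented as a known
approximation; the first tract of each chromosome draws from f.)
Tract-level distributional correctness is verified against numerically
integrated coalescent CDFs and against msprime pairwise coalescence
times.

**Variants.** Heterozygous SNVs arise per site with probability 2μT on
each tract (rejected if μT ≥ 0.5, where the small-rate approximation
breaks); homozygous SNVs model fixed differences at the configured
divergence (default 0.4%). Substitutions are transitions with
probability R/(R+1), R = 2.39 by default. Small indels are uniform at
3×10⁻⁴/site (≈1 M in a 3-Gb genome, as observed), 60% deletions,
geometric lengths truncated to the caller's detectable windows. Large
indels and inversions are planted explicitly.

**Evidence.** Pileups draw Poisson(41.5) depth per site; each read
picks one allele with probability ½ and is misread with probability ε
(default 0.01) uniformly to the other three bases. Sequencing indel
errors are not simulated; small-indel evidence instead carries explicit
support counts (binomial with success ½ for het, 0.95 for hom
carriers). Mate pairs are placed uniformly on the *sample* genome with
inserts uniform in the library range (600–800 and 800–1,000 bp), then
mapped back: deletions inflate and insertions deflate the observed
span, tags inside insertions are unmappable, and fragments straddling
an inversion breakpoint are flagged orientation-incongruent (the flag
stands in for platform-specific tag-orientation logic). The default
span coverage knob is 40×; `STUDY_PHYSICAL_COVERAGE` records the values
implied by the study's library table (≈48× and ≈86×), used where
study-scale inversion-window counts matter.

**What the engine does not emulate:** read-level sequences and mapping
artifacts, mapping-quality structure, base-quality miscalibration,
indel sequencing errors, CpG and mutation-rate heterogeneity,
multi-population samples, and correlated errors near SVs. Passing
recovery tests therefore demonstrates correctness of the algorithms
under the stated generative model, not performance on real reads.

## Genotype calling

Each site's ten unordered diploid genotypes are scored with a
binomial-mixture read model (allele chosen with probability ½, misread
with probability ε to a uniform other base). The prior puts
1 − h − d on hom-ref, h (default 0.003, the macaque per-site
heterozygosity scale) split over the three ref-containing
heterozygotes, d (default 0.004, the divergence scale) over the three
hom-alts, and a doubly small h·d mass over ref-free heterozygotes; the
vector is renormalised. Call quality is −10·log₁₀(1 − p_MAP), capped
at 99. If the two most probable genotypes disagree on zygosity with a
posterior ratio under 10, the call is `ambiguous` and excluded from SNV
counts — an explicit stand-in for the upstream caller's undocumented
ambiguity class. Exact ties break toward the zygosity-conservative
class (hom_ref > het > hom_alt). The likelihood is verified against
exhaustive enumeration over read-to-allele assignments up to depth 12,
and the vectorised bulk caller against the scalar path site by site.

Variant filters mirror the study: depth ≥ 5, call QV ≥ 40, reference
assembly QV ≥ 45, with rejections tallied by first failing rule in
that order. On a hemizygous male X, heterozygous calls are excluded.
The discovery-rate profile (callable sites and het/hom SNV rates per
reference-QV value) is computed *before* the reference-QV filter, since
it is that filter's diagnostic.

## Annotation, comparison and population genetics

Transcript models are validated (CDS length divisible by 3, no internal
stop, in bounds; genes at multiple loci dropped entirely — the three
checks are an explicit choice where the original's "inconsistencies"
are undefined; start codons are not checked). Site classes follow the
priority coding exon > non-coding (UTR) exon > intron > intergenic over
all overlapping transcripts; coding SNV effects are per-codon
translations (standard nuclear code, reverse-complemented on minus
strands), verified against whole-CDS before/after translation; coding
indels are frameshift unless their length is a multiple of 3. Variants
spanning a class boundary take the class of their leftmost base.

Panel comparisons (shared, merged, private, completely differentiated
SNVs; heterozygous-sharing fractions) are set operations keyed on
(position, alternate allele). "Completely differentiated" takes the
strict reading: every member of both species groups homozygous, no
missing calls, groups fixed for different alleles (an `allow_het`
switch relaxes it). Sites where any other individual is missing cannot
establish privacy and are dropped from private-SNV counts.

π is the heterozygous fraction of callable sites; d_xy adds half the
heterozygous to the homozygous fraction (the reference contributes one
chromosome). The between-species N/S ratio uses hom + ½·het weights for
consistency with d_xy (raw pooled counts are one flag away). The χ²
test is Pearson without continuity correction — at the study's counts
the correction is irrelevant — with p from the regularised incomplete
gamma function and independently checked against scipy.

## Structural variants

Small-indel candidates (del < 12 bp, ins < 4 bp, the gapped caller's
limits) need ≥ 3 supporting reads and reference QV ≥ 45; zygosity is
hom at supporting fraction ≥ 0.75. Large indels come from mate-pair
spans outside the library insert range; same-sign discordant pairs are
clustered while their inner gaps keep a common intersection, and a
cluster of ≥ 3 pairs is called with size |median span − insert-range
midpoint| — robust to outliers, and unbiased to within the insert-range
half-width on planted events. The call interval is the inner-gap
intersection, widened to at least the size estimate when it collapses
to a sliver: breakpoint uncertainty is of the order of the event size,
and without the widening the ≥ 50% reciprocal-overlap merge rule fails
to join the same insertion seen through two libraries. Cross-library
merging is transitive (connected components) with support-weighted
sizes. Inversion screening counts incongruent pairs whose leftmost tag
falls in 500-bp windows sliding by 250 bp; windows with ≥ 50 such pairs
are flagged.

## Demographic inference

The genome is reduced to 100-bp bins: `K` if the bin holds a retained
heterozygous call, `N` if less than half its bases are callable, `T`
otherwise. The HMM state is the discretised TMRCA interval on an
exponential grid t_k = α(exp(k/n·ln(1 + t_max/α)) − 1) with α = 0.1 and
t_max = 15 (scaled units of 2N₀ generations; >1 Myr at macaque
parameters). Atomic intervals are tied into groups by a pattern string
("6+29*2" → one group of 6 plus 29 groups of 2, 64 atomic intervals).
Each interval carries the mean of the coalescent density truncated to
it (the last interval is open-ended); emissions are
P(K|k) = 1 − exp(−θ·t̄_k); the chain stays with probability
exp(−ρ·t̄_k) and otherwise jumps to an interval drawn from the
length-biased prior π_k·t̄_k — the stationary counterpart of the tract
simulator, so the chain's marginal state distribution is the plain
coalescent mass π. This is deliberately PSMC-lite: the full PSMC
conditional transition integral is replaced by the stationary jump
approximation, and the exhaustive-path oracle in the tests guards the
implemented model, not PSMC itself.

Fitting is EM with scaled forward-backward (forward variables
normalised per bin; the rank-one-plus-diagonal transition gives O(n)
recursions, with dense expected-transition counts accumulated for the
M-step). The M-step maximises the expected complete-data log-likelihood
numerically (L-BFGS-B on log-λ and log-θ) because λ enters prior,
transition and emission jointly through t̄; the update is accepted only
when it improves the objective, making this a generalised EM with a
non-decreasing log-likelihood. ρ is held fixed at θ₀/5 (joint
estimation is unstable at desk-scale data). θ₀ is initialised from the
K-bin fraction via θ₀ = −ln(1 − f_K). Scaling uses
N₀ = θ/(4μ·bin), N_k = N₀λ_k, years = 2N₀·t·g with μ = 2.5×10⁻⁸ and
g = 6 by default. Confidence intervals are percentile block bootstraps
(5-Mb blocks resampled with replacement, refit, default 20 replicates
at desk scale versus 200 in the study).

Problem sizes used by the shipped checks: 10 Mb for calling/diversity
recovery, 25 Mb (5 × 5 Mb chromosomes) for the three-epoch bottleneck
refit, 4 Mb for bootstrap-coverage checks — sizes at which the checked
tolerances (3 Monte-Carlo SE; factor 2 on middle-epoch sizes) are
well inside the expected fluctuation of the quantities.

## Numerical and convention notes

- Coordinates are 0-based half-open internally; VCF/GFF3 conversion at
  the IO boundary only. Truth VCFs written by the simulator are
  synthetic data, labelled as such by provenance.
- Percentages round half-up (matching the summary tables' style).
- Summary totals are exact column sums; where a printed source total
  disagrees with its own rows, the column sum is reported.
- The macaque recombination rate is unreported; the default
  ρ = 1×10⁻⁸/site/generation is a conventional primate-scale
  placeholder, exposed in the configuration.
- RNG: one root seed; each stage derives an independent stream from a
  CRC-tagged SeedSequence, so outputs are bytewise reproducible and
  stages can be re-run in isolation.

## Known limitations

- The genotype caller has no mapping-quality model (the evidence model
  carries none) and no indel realignment or base-quality recalibration.
- Plain-SMC full resampling understates the correlation between
  consecutive tract times; the demographic model shares the
  approximation, so recovery tests do not probe it.
- Oldest and youngest time intervals of the demographic fit are weakly
  constrained at tens of megabases; headline recovery claims are
  restricted to the well-constrained middle of the grid.
- The inversion screen locates breakpoints only to window resolution
  and does not attempt split-read refinement.
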