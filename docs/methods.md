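# Methods

This note records the models implemented in `dloopdyn`, their assumptions,
the numerical choices made where the design was open, and what the synthetic
data do and do not establish.

## Data model

A sample is a gapped sequence over `{A, C, G, T, ?}` on explicit 1-based
reference-mitogenome coordinates covering the two amplified d-loop blocks
(15,492–15,669 and 15,696–15,758, at most 241 columns). Alignment length is
data-driven (≤ 241 columns) rather than hard-coded, because real assemblies of
this region vary by a column depending on indel handling. `?` is the only
missing-data symbol; IUPAC ambiguity codes are rejected on input and never
produced — a consensus tie becomes `?`, since every downstream statistic is
defined on `{A, C, G, T, ?}` only. Ages are normalised to calendar years BP
(inputs below 100 are read as ka).

Replicate-read consensus calls a column when ≥ `min_reads` (default 3)
non-missing reads from ≥ `min_extractions` (default 2) independent extractions
cover it and one base holds a strict majority; anything else is `?`. This is
deliberately conservative: ancient-DNA miscoding lesions make a 2-vs-2 tie
uninformative.

Three dataset rules reflect how such studies stratify quality: all samples;
samples with ≤ 40% missing columns; directly radiocarbon-dated samples only.
Bins follow archaeological culture; a pooled Magdalenian+Azilian bin (union,
not part of the partition) is produced except under the dated-only rule,
where the separate bins are clean by construction.

## Diversity under missing data

Two deletion conventions are implemented because both are in field use and
they do not generally agree:

* *pairwise deletion*: each pair is compared over its mutually non-missing
  columns and the raw count rescaled by `L / L_ij`; a pair with no overlap is
  an error rather than a silent zero.
* *column threshold*: columns with > q missing (default q = 0.05) are removed
  first, then pairwise deletion on the survivors.

Distances are raw p-distances; at d-loop divergences of a few percent,
substitution-model corrections change nothing of interest and would break
comparability with the haplotype-level treatment. Every report records which
convention produced each number.

Haplotype collapsing offers `strict` (a `?` never matches) and `compatible`
(`?` matches anything; a sequence joins the first compatible haplotype in
input order, filling its gaps). `compatible` is the default because partial
ancient sequences are conventionally counted as members of known haplotypes;
`strict` exists for sensitivity analysis. The haplotype count — and hence
Fu's F_S — depends on this choice for gappy data.

## Neutrality and expansion statistics

**Tajima's D** uses the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂).
With S = 0 the statistic is reported as undefined, not 0. At n = 3 the
variance estimate collapses to zero; a simultaneously zero numerator is
reported as D = 0 (the limit), otherwise undefined. The p-value comes from
≥ 1000 coalescent simulations conditional on the observed S (mutations
dropped uniformly on the genealogy by branch length), one-tailed toward
negative D with a two-tailed option. Conditioning on θ̂ instead is available
via `condition="theta"`.

**Fu's F_S** computes S′ = Pr(K ≥ k_obs | θ̂, n) exactly under the Ewens
sampling distribution, with unsigned Stirling numbers of the first kind from
the recurrence |s(n+1,k)| = n|s(n,k)| + |s(n,k−1)| evaluated entirely in log
space (stable beyond n = 100). θ̂ is the observed mean pairwise difference.
S′ = 1 yields F_S = +∞, flagged. The p-value is the fraction of neutral
coalescent replicates (conditional on n and θ̂) with F_S* ≤ F_S; reports note
the customary p < 0.02 significance convention for this statistic.

**Mismatch and stepwise expansion.** The mismatch distribution is the exact
histogram of (rounded, rescaled) pairwise differences, at sample level by
default or between distinct haplotypes on request. The expected distribution
under a stepwise expansion from θ₀ to θ₁ at mutational time τ = 2uT is

    F_i(τ, θ0, θ1) = F̂_i(θ1) + e^{−τ(θ1+1)/θ1} Σ_{j=0}^{i} (τ^j / j!) [F̂_{i−j}(θ0) − F̂_{i−j}(θ1)],

built on the equilibrium geometric F̂_i(θ) = θ^i/(1+θ)^{i+1}. The
implementation factors the exponential as Pois(j; τ)·e^{−τ/θ₁} and evaluates
the geometric terms in log space. Self-consistency holds at both limits
(τ = 0 returns the θ₀ equilibrium, τ → ∞ the θ₁ equilibrium). Parameters are
fitted by bounded least squares on (τ, θ₀, θ₁ − θ₀) with three starts (a
moment start τ ≈ mean mismatch plus two alternatives); SSD is the objective.
Harpending's raggedness is r = Σ_{i=1}^{d+1}(x_i − x_{i−1})² with x_{d+1} = 0.
p-values for SSD and r come from a parametric bootstrap: simulate under the
fitted parameters (coalescent with a population-size step at τ̂/θ̂₁ and
ancestral relative size θ̂₀/θ̂₁, clamped at 10⁻⁹), refit each replicate, and
report the upper-tail fractions with the +1 correction.

## The internal coalescent

Null distributions, bootstraps and the data generator share one Kingman
coalescent with piecewise-constant size. Units follow the mismatch-analysis
convention for haploid loci: time in units of the present population size N₁
(generations), mutation rate θ/2 per lineage per unit time, expansion at
coalescent time τ/θ₁ with relative ancestral size θ₀/θ₁. Mutations are
placed on branches in proportion to branch length, each on a fresh site
(infinite sites), either a fixed number (conditioning on S) or
Poisson(θ·L_total/2). The engine is validated in the test suite against
closed forms (E[S] = θa₁, E[L] = 2Σ1/i, E[π] ≈ τ + θ₀ post-expansion) and
against msprime as an independent simulator.

## Differentiation

Φ_ST is the two-level AMOVA variance decomposition on the matrix of pairwise
differences (used directly as squared distances, the Arlequin convention for
haplotypic data): σ²_a/(σ²_a + σ²_b) with the unequal-sample-size coefficient
n_c = (N − Σn_p²/N)/(P−1). Negative estimates are reported as computed, not
clamped, to preserve comparability with standard software output. The
permutation test shuffles individuals between the two bins;
p = (1 + #{Φ* ≥ Φ})/(n_perm + 1), default n_perm = 10,000, bit-reproducible
given the generator. All sequences identical is flagged undefined.

PCA of relative haplogroup frequencies is covariance-based (rows centred,
not scaled) via SVD; variance shares are reported over the retained
min(rows − 1, columns) components and sum to 1.

## Sample-size-bias randomization

The pooled-resampling test resamples *with replacement* — honouring the
published description literally — pseudo-groups of the original bin sizes
from the pooled sequences, collecting π and h for each (a without-replacement
permutation split is available as an option). Per bin, a two-sided empirical
tail probability of the observed value within its own-size pseudo
distribution is reported (with the +1 correction); the comparison is flagged
biased when either p < α = 0.05. Both statistics are always computed and
flagged separately, never combined. Because the tail convention is not fixed
by the verbal description, the pseudo distributions themselves are exported
(and optionally plotted as two-panel densities) so users can apply their own
read-out. Haplotype classes and the pairwise-deletion distance matrix are
precomputed once on the pool, so each replicate is pure index arithmetic;
note this fixes the haplotype partition at pool level, a deliberate
approximation that makes 10k replicates cheap and is exact for complete data.

## Median-joining networks

Distances are weighted Hamming distances over the columns with no missing
data in the haplotype set (the convention of the standard network software;
imputation is out of scope). Site weights are `max(1, round(50 / k_c))`
where k_c is the number of state changes at column c — estimated as
(distinct observed bases − 1) unless the caller supplies change counts — and
columns whose polymorphism involves a transversion weigh 10× transition
columns. The exact published per-position weights of the motivating study
are not recoverable, so figure topology is a qualitative, not bit-exact,
target.

The network construction iterates: (i) build the ε-relaxed minimum spanning
network (at ε = 0, the union of all minimum spanning trees); (ii) for every
connected triplet propose the per-column majority-consensus median (Steiner)
vector; (iii) accept a median iff it strictly reduces the total MSN weight
over the node set — this acceptance rule makes the total length monotonically
non-increasing and guarantees termination (cap: 50 rounds); (iv) at fixpoint,
prune inferred nodes of degree ≤ 2 whose removal does not lengthen the
network. By construction the final graph is an MSN over its node set, hence
contains a minimum spanning tree of the observed-plus-median nodes.
Three-way ties in the median default to the first pattern; such columns
cannot shorten the network either way. Temporal sub-networks keep the full
topology per bin, mark haplotypes absent from the bin as empty placeholders,
and flag nodes shared with the next bin as continuity links.

## Synthetic data

The generator emulates the statistical structure the analysis assumes: a
shared random reference sequence; per-bin coalescent genealogies (constant
size or stepwise expansion in τ/θ units) with infinite-sites mutations
scattered over the finite column set under a 10:1 transition:transversion
bias; optional planting of haplogroup-defining states; and block-structured
missingness centred on reference positions 15,564–15,669, applied
missing-completely-at-random at the sample level. Bins are independent demes
(no shared genealogy across bins), which mirrors the discontinuous,
replacement-dominated history the pipeline is designed to detect, and makes
between-bin Φ_ST values substantial by construction; panmictic null scenarios
are obtained by splitting a single simulated bin.

The 97-sample study fixture reproduces the design of the motivating dataset
exactly: bins 4/11/70/4/8 (pooled Magdalenian+Azilian = 74), eight planted
haplogroups including an X4b-bearing lineage, 27 samples with missing blocks
of which 19 exceed the 40% threshold (leaving 78 with bins 4/11/53/4/6), and
directly-dated flags 4/5/20/3/4 (36 samples). Defaults elsewhere use the
quality-filtered bin sizes (4/11/53/4/6) and θ = 5, a typical d-loop value
for these data (π ≈ 0.01–0.02 over ~240 bp).

What the synthetic data do **not** contain: post-mortem damage (deamination)
patterns, sequencing error, reticulate or recurrent mutation beyond the
finite-column placement, heterochronous sampling within a bin, or real
haplogroup definitions beyond X4b (the shipped A–X3 entries are synthetic
placeholders; users supply published definition tables). Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not the wet-lab robustness of any particular empirical result.

## Haplogroup classification

A definition matches iff every mandatory (position, base) is observed
(non-missing and equal to the derived state); optional positions are free.
Hotspot columns (15,585; 15,604; 15,650) are dismissed before matching, so
assignments are invariant to any substitution there. Missing data at a
mandatory position makes a definition undecidable → `unassigned` with reason
"insufficient data"; several matches → `ambiguous` with the candidate list.
Because the published account leaves the mandatory/optional split of X4b
partly ambiguous, the shipped table makes 15,540 mandatory and
15,495/15,602/15,718/15,720 optional, and the classifier reads definitions
from file so users can override any of it.

## Problem sizes and numerical defaults

Production defaults: 10,000 permutations/resamples for Φ_ST and the bias
test; 1000 null replicates for D and F_S; 100 bootstrap refits for SSD and
raggedness. The test suite and the acceptance script use smaller,
fixed-seed versions of the calibration experiments (e.g. 500-replicate bias
resampling, 200-replicate expansion recovery with 200-replicate null
p-values) — sizes chosen so the whole suite runs in a couple of minutes while
keeping Monte-Carlo error well inside the asserted tolerances. Every
simulation consumes an explicit `numpy` Generator; the pipeline derives
per-stage substreams from one master seed via CRC-keyed `SeedSequence`, so
reruns are bit-identical.

## Known limitations

* Fu's F_S p-values are simulation-based conditional on θ̂; for very small θ̂
  the null distribution is coarse.
* The expansion fit's SSD surface is flat in θ₁ for star-like data; τ̂ is the
  well-identified parameter (and the only one asserted in recovery tests).
  τ̂ carries the usual upward finite-sample bias of moment/LS fits.
* The MJN is exact only in the sense of its stated greedy acceptance rule;
  for large ε or many near-ties it can differ from other published
  heuristics.
* Φ_ST assumes exchangeable haploid sequences within bins; heterochrony
  within a bin is ignored.
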