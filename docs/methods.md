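# Methods

## The screen model

We model a phenotype-sequencing experiment as S independent mutant
strains, each of which passed a phenotype screen. Mutations arise
independently over the genome, so the number of mutations in any region
with expected count λ is Poisson. The screen requires at least one
mutation in the *target region* (the union of the T genes in which a
mutation can cause the phenotype, with total per-strain rate
λ_T = Σ_targets λ_g), which conditions the per-strain target count on
m ≥ 1:

    P(m | screen) = Poisson(m; λ_T) / (1 − e^(−λ_T)),  m = 1, 2, …

The sum over S strains is sampled as a single multinomial draw of S
counts over the truncated support of this distribution (cost
O(support), not O(S)); the total K is then allocated across target
genes by a multinomial with probabilities proportional to each gene's
effective size. Non-target genes accumulate counts as plain Poissons
with mean S·λ_g; to avoid per-gene work at genome scale the genes are
sorted by size into B bins (default 10) of ⌊G/B⌋ genes each, remainder
genes joining the last (largest-size) bin — a deliberately conservative
placement since it slightly inflates the large-gene bin — and each bin's
gene-count histogram is one multinomial draw over a truncated Poisson.

Truncation: Poisson supports are cut where the remaining tail mass
drops below `tail_mass_cutoff` (default 1e-10) and renormalised to sum
to exactly 1. At this threshold the truncation error is far below every
statistical tolerance used anywhere in the package.

*Effective target size.* "Size" aggregates everything that affects a
gene's chance of being hit: length and base composition. We use
λ_g = n_GC·μ_GC + n_AT·μ_AT with per-base rates measured genome-wide.
Chemical mutagenesis with NTG is strongly G:C-biased (observed rate
ratio around 36), so two genes of equal length can differ several-fold
in effective size.

*Conditioning scope.* The screen condition is applied to the target
region only; non-target genes are sampled unconditionally. A strain's
acceptance is in truth weakly correlated with its total mutation count,
but for realistic λ_T the induced inflation of non-target counts is
below one part in a thousand and is ignored.

*Density conventions.* When an experiment is described by total
mutations per genome, the non-synonymous density is taken as 2/3 of the
total (random coding changes are non-synonymous about two-thirds of the
time); scoring restricted to non-synonymous SNPs should use that
density.

## Sequencing-error model

Pooling P strains dilutes a real mutation to an expected read fraction
(1 − ε)/P, where ε is the probability of reading one *specific* wrong
nucleotide (about a third of the total miscall rate; no ×3 factor is
applied anywhere, since only the specific erroneous base competes with
a given variant call). With integer coverage n = round(c):

- detection failure (false negative): P(X < k), X ~ Binom(n, (1−ε)/P);
- per-site false positive: P(X ≥ k), X ~ Binom(n, ε), expected
  genome-wide count = rate × genome length.

Injection into the simulator: the target multinomial is rescaled by
(1 − ν) with an appended discard category of mass ν (detection
failure); each target gene additionally receives Poisson false calls
with mean L_g·τ; each non-target gene's total expected count becomes
S·λ_g·(1 − ν) + L_g·τ. The false-positive intensity is applied once per
experiment per gene, which keeps target and non-target genes under the
same false-call model; at any sensible call threshold τ·L_genome < 1,
so this choice is numerically immaterial — it only shapes the
false-positive "flood" at very low thresholds.

Local coverage variation is not modeled: at the genome scale,
above-average-coverage regions offset below-average ones, and the rates
computed from mean coverage are accurate to first order. This is a
documented limitation; the synthetic generator has an optional
negative-binomial depth mode (off by default) for robustness testing.

Multi-lane designs: rates above are per lane. A two-of-three-lanes
concordance rule turns a per-lane failure rate ν into an effective
3ν²(1 − ν) + ν³, and a per-lane false-positive rate τ into roughly τ²
(same site, same alternate base twice); the yield predictor accepts an
explicit error profile for such cases.

## Scoring and yield

A gene with m observed mutations is scored against the non-target null
by the Poisson upper tail p = P(X ≥ m | S·λ_g); m = 0 gives p = 1
exactly. Bonferroni correction multiplies by the number of genes
observed mutated at least once (default; a flag switches to all
annotated genes, since both conventions are defensible) and caps at 1.
Ranked tables break ties deterministically: p ascending, then hit count
descending, then gene id.

*Yield at FDR.* With equal gene sizes the reported list is a
count-threshold: the smallest m\* such that for every m ≥ m\* the
fraction of non-targets among genes with ≥ m mutations is strictly
below the FDR; the yield is the number of targets with ≥ m\* mutations
(0 if no threshold qualifies). With variable sizes the same rule runs
on the p-value ranking: the largest cutoff p\* such that the non-target
fraction among genes with p < cutoff stays below the FDR at that and
every stricter observed cutoff. The two rules coincide when sizes are
equal. Note the yield statistic uses truth labels — it is a property of
simulated or validated experiments, not something computable from field
data alone.

*Calibration diagnostic.* Sampling non-target counts under the null
(default: 50 mutations/genome, 4244 genes, 80 strains, 1000 replicates),
computing p-values, sorting, and plotting −log p against the negative
log of the empirical rank fraction (i + 1)/N (0-based i; the faithful
point of a tie block is its last element) gives the y = x diagonal for
uniform sizes. For variable sizes the curve sits on or above the
diagonal: a large gene's near-1 p-value understates how often small
genes reach the same count, so the p-values are slightly conservative.
Ten size classes approximate the exact size distribution closely, which
justifies the binned non-target sampler.

## Experiment design arithmetic

Costs are exact rational arithmetic: total = libraries × lib\_cost +
lanes × lane\_cost (defaults $50 and $700), with libraries = ⌈S/P⌉ (an
explicit mixed pool-size list, e.g. eight pools of 3 plus two of 4, is
also supported) and fractional lanes allowed (⌈·⌉ by flag). Coverage
per library = lane capacity / (genome length × tag\_pool), reported
unrounded and rounded only for display.

`optimize_design` scans P upward at each tag-pool level, at each step
picking the call threshold k by maximising simulated mean yield over a
window starting at the smallest k whose expected genome-wide false
positives fall below one, and stops when the mean yield drops below a
configurable fraction (default 90%) of the unpooled yield by more than
two standard errors — the tolerance prevents replicate noise from
truncating the scan early. "High yield maintained" is not given a
number by the underlying theory; 90% is this package's operational
choice and is exposed as a parameter.

## Synthetic data

The generator emulates the study conditions end to end: a toy annotated
genome (default 40 non-overlapping CDS of mean 900 nt, ~20% intergenic,
GC fraction 0.5, start/stop codons stamped per strand); strains drawn
forward (n ~ Poisson(θ), default θ = 50 total mutations per genome,
sites chosen with GC/AT rate ratio 36, alternate base uniform over the
three possibilities) with whole-strain rejection until ≥ 1 target-gene
mutation; and pooled VCFs at fixed per-site depth c where true variant
sites draw Binom(c, carriers·(1−ε)/P) supporting reads, every other
site draws Binom(c, ε) error reads for one random wrong base, and a
site is emitted at ≥ k alternate reads with AF = alt/depth. The default
k is the smallest threshold with expected genome-wide false calls below
one. Parental variants can be planted at AF 1.0 in every library.

What the fixtures do **not** emulate — and hence what passing tests do
not establish about field data: read-level artifacts (base qualities,
mapping bias, indels, structural variants), depth heterogeneity along
the genome, correlated errors between lanes, and caller-specific
allele-frequency estimation. The pipeline consumes standard VCFs, so
those effects enter only upstream of this package.

## Problem sizes and numerical choices

Simulated checks use 1000 replicates for reference yields and threshold
scans, 100 end-to-end synthetic experiments for pipeline-versus-model
consistency, and 10k replicates where a distributional oracle
(rejection sampling, chi-square at α = 0.01) is compared; these sizes
give standard errors comfortably inside every asserted tolerance.
Binomial tails come from scipy and are verified against exact
integer-arithmetic summation to 1e-12. All stochastic operations take
an explicit `numpy.random.Generator`; nothing reads global RNG state,
and fixed seeds reproduce byte-identical outputs.

## Known limitations

- Strains are assumed conditionally independent given the parent
  (star phylogeny); shared post-ancestral history would need per-strain
  tagging and phylogeny-aware counting, which pooling forfeits.
- Single-nucleotide substitutions only; indel and IS-element events are
  out of scope.
- The Bonferroni multiplier convention and whether expected counts
  should use coding span or whole-gene span are both exposed as options
  rather than fixed, as neither is uniquely determined by the theory.
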