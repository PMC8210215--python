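# Methods

## Scope and conventions

`regmut` analyses somatic single-nucleotide variants (SNVs) within small
genomic region sets. All internal coordinates are 0-based half-open;
conversion to the 1-based conventions of mutation TSV and VCF files
happens only at the I/O boundary. Region sets are BED3: strand is never
stored, since the analyses are strand-symmetric (all substitution and
trinucleotide accounting collapses onto the pyrimidine-referenced
strand). Non-SNV input records (indels, multi-allelic sites) are skipped
and counted; a mutation whose declared reference base disagrees with the
genome is skipped with a warning rather than aborting the run, because
public catalogs contain liftover noise.

The 96 channels follow the COSMIC ordering: six substitution blocks
C>A, C>G, C>T, T>A, T>C, T>G, each with 16 flank contexts sorted by 5'
then 3' base (A < C < G < T). The 32 pyrimidine-centred trinucleotides
are ordered analogously.

## Distance-based views

Regions are aligned on their central points, ⌊(start + stop)/2⌋.
Windows cover center ± h inclusive (odd length, symmetric offsets). The
default half-width h is the size of the largest region in the set,
floored at 1000 bp and capped at 5000 bp, so the whole window is double
the largest region within those limits. A mutation under several
overlapping windows contributes once per window in distance-based views
(each window is its own alignment); intersection-based views instead
count each physical mutation once.

Histogram bins are left-closed: offset o falls in the bin starting at
⌊o / bin_size⌋ · bin_size. For bin_size > 1 the reported coordinate is
the bin start; offset 0 is the center base. Base-change filters such as
`C>T` or `C>*` match the stated change or its reverse complement by
default (a C>T on either strand is the same chemical event); this
collapsing can be disabled.

Fold-enrichment profiles divide each bin's observed count by the
expected count under the window-average rate, i.e. the total mapped
count distributed proportionally to the number of window positions each
bin covers. The position-weighted mean of the profile is therefore one
by construction; an empty input yields an explicitly undefined profile.

## Local-enrichment permutation test

Under the null, each mapped mutation is equally likely to sit at any of
the 2h + 1 positions of its window, so its probability of landing in the
target is q_w = target_length / (2h + 1), and a permutation's in-target
count is a sum of independent Binomial(n_w, q_w) draws over windows. The
test samples this distribution directly — the exact distribution of
uniform re-positioning, without enumerating positions — with a seeded
generator, so results are bit-reproducible. The p-value is the plain
fraction k / n_permutations of permutations whose count reaches the
observed one (≥ for hypermutation, ≤ for hypomutation; both tails
include equality, so p_hyper + p_hypo ≥ 1). When k = 0 the result
carries a lower-bound flag and is displayed as "< 1/n_permutations";
the (k+1)/(n+1) estimator is deliberately not used, to match the
reporting convention of the fraction-of-permutations definition.
Discreteness of the in-target count makes the test slightly
conservative at small mutation counts.

## Chi-squared comparison

Two conditions (region sets or tumor types) are compared on the 2×2
table of per-base rates [[f₁, r₁], [f₂, r₂]] with Pearson's test of
independence, df = 1, no continuity correction. Rates are used exactly
as defined — mutations per base in flanks and targets — without any
rescaling to pseudo-counts; the statistic is therefore scale-dependent
in the totals, which is inherent to the definition. A zero row or
column marginal makes the test undefined and raises an error.

## Trinucleotide accounting and signature adjustment

Opportunity counting slides a 3-mer window over each merged region's
forward-strand sequence; 3-mers must lie fully inside a region (no
flank leakage — R defines the opportunity set), 3-mers containing N are
skipped, and purine-centred 3-mers count toward their reverse
complement, mirroring the channel collapse: a C>T observed on either
strand must be matched by opportunity counted on either strand.
Overlapping regions are merged first so opportunity is never counted
twice.

Correction factors are c_t = freq_R(t) / freq_G(t) over the 32
collapsed trinucleotides. If t is absent from both R and G, c_t = 1; if
absent from G but present in R the inputs are inconsistent and an error
is raised. Signatures are adjusted channel-wise, s'(j) = c_{t(j)} s(j),
then renormalized; when every c_t equals 1 the original signature
object is returned unchanged so the identity is exact. A signature
whose entire support falls on absent trinucleotides becomes degenerate
and raises an error naming it.

## Refitting

Exposures minimize the unweighted squared error between the observed
channel fractions and the exposure-weighted signature mixture, subject
to non-negativity and sum-to-one. The solver is a deterministic
active-set method on the KKT system: start from the full support, solve
the equality-constrained least-squares subproblem, drop the most
negative exposure, and re-admit any excluded signature whose reduced
gradient is negative; a scipy SLSQP minimization is kept as a fallback
for numerically degenerate inputs. The reported residual is the squared
distance between the observed fractions and the fitted mixture.

Cohort results fit each donor separately (donors below a configurable
minimum in-region mutation count, default 1, are excluded but reported)
and report the arithmetic mean of per-donor exposure vectors alongside
per-signature distribution summaries; a pooled single-spectrum fit is
available as the non-per-donor path. The mean of simplex vectors is
itself on the simplex.

## Synthetic data generator

The generator emulates the full input stack: an i.i.d. random genome
with configurable base composition, non-overlapping planted regions
(optionally overwritten with a repeated motif to skew their
trinucleotide content), donor metadata (sex, age, first therapy type),
and mutation catalogs drawn from known signature mixtures.

Mutation sampling is site-constrained. For each mutation: (1) the
compartment — region set or remainder of the genome — is chosen by a
Bernoulli draw with odds (enrichment_factor · q) : (1 − q), where q is
the regions' share of valid trinucleotide sites (a site is in-region
when its whole 3-mer lies inside a merged region, matching the
opportunity rule); (2) the channel is drawn from the exposure-weighted
mixture of signatures adjusted to that compartment's trinucleotide
content; (3) the position is drawn uniformly among the compartment's
sites matching the channel's trinucleotide, and ref/alt are written on
the strand the genome actually shows. Channels whose trinucleotide has
no site in the chosen compartment are resampled and counted. Under this
model the in-region spectrum is exactly the exposure-weighted mixture
of region-adjusted signatures — precisely the generative model the
refitting estimator assumes — so parameter-recovery experiments test
the solver and the adjustment rather than model mismatch. Sites are
drawn with replacement; at desk scale (10⁴–10⁵ bp genomes, 10²–10³
mutations per donor) occasional position collisions are harmless for
every statistic computed here.

Ground truth (exposures, per-donor in-region/flank counts, enrichment
factor, seed) is written alongside the catalog. All randomness flows
from a single seed through fixed per-stage child streams, and every
simulation is bit-reproducible.

What the generator does **not** emulate: chromatin- or
replication-timing-dependent mutation-rate covariates, doublet (CC>TT)
and indel events, sequencing artifacts, or subclonal structure. Passing
tests on synthetic data therefore demonstrate the correctness of the
estimators under their stated model, not robustness to those real-data
features.

## Study conditions used by the checks

The acceptance script and the deep tests use fixed desk-scale
conditions chosen once: calibration of the permutation test uses 200
uniform-null datasets of 500 mutations over twenty ±1 kbp windows with
201 bp targets at 1000 permutations each; the binomial-oracle check uses
a single window at 10 000 permutations; refit optimality compares 50
random spectra against the full 0.01-step three-signature simplex grid;
exposure recovery uses 20 donors with 2000 in-region mutations each
(enrichment factor 10⁶, so effectively all simulated mutations fall in
regions) and true exposures 0.6/0.3/0.1; the adjustment-benefit check
uses 50 donors of 300 in-region mutations on regions overwritten with a
CpG-rich motif, paired per-donor errors, and a one-sided sign test.

## Numerical choices and limitations

- Signature columns off unity by ≤ 10⁻³ are renormalized with a warning;
  larger deviations are errors. Signatures store float64 and must sum to
  1 within 10⁻⁸ after normalization.
- The active-set solver treats exposures below 10⁻¹¹ as zero and checks
  reduced gradients at 10⁻⁹; ties in the drop step resolve to the first
  minimal index, making results deterministic.
- Donor predicates compare ordered operators numerically and equality
  textually (with a numeric fallback); a comparison on a field a donor
  lacks excludes that donor, and a field unknown to every donor warns
  and matches nothing.
- Windows extending past chromosome ends are not clipped; the
  permutation null assumes all window positions exist. For region sets
  near chromosome boundaries, supply an explicit smaller half-width.
- The χ² comparison inherits the scale-dependence of per-base rates;
  p-values across datasets of very different sizes are not directly
  comparable.
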