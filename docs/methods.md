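# Methods

This note records the models implemented in `readcoal`, the conventions and
defaults, the numerical choices, and what the synthetic-data tests do and do
not establish about real data.

## Units and the species network

All times and rates are in expected substitutions per site.  A population
with size parameter θ = 4Nμ has pairwise coalescent rate 2/θ; a species
divergence at τ merges the daughter populations into the ancestor.  Every
branch of the species tree is a population and may carry its own θ; the
bundled presets assign a single global θ and divergence times proportional to
it, so θ acts as a pure mutation-rate scale.

Presets `B` and `U` are five-species trees for species-tree benchmarking
(B: `(((A,B)t,C)s,(D,E)u)r` with τ = {5, 4.8, 4.7, 4.8}·θ; U:
`((((A,B)u,C)t,D)s,E)r` with τ = {5, 4.8, 4.6, 4.4}·θ).  The gene-flow
presets (`*-IM`, `*-MIG`) use τ = {5, 4, 3, 4.5}·θ (B) or {5, 4, 3, 2.5}·θ
(U) with two gene-flow events B→C and D→E at strength φ = 0.3/0.2 or
M = 0.3/0.2.  The extracted sources state the trees' internal branch lengths
and which events connect sister versus nonsister lineages but not the tip
label placement; the preset topologies are the unique shapes consistent with
both constraints, and no shipped quantity depends on the label placement.

Gene flow comes in two exclusive flavours.  An introgression event (MSC-I)
is instantaneous: backwards in time, each lineage present in the recipient at
the event time jumps to the donor branch with probability φ.  A migration
band (MSC-M) is continuous: M = Nm migrants per generation translate to a
backward per-lineage jump rate of 4M/θ_recipient per unit mutational time
(from M = Nm and θ = 4Nμ), active only while both populations exist.  Events
inside each inter-τ epoch are scheduled by competing exponentials
(coalescence versus migration); population merges and introgression routing
are deterministic events at their τ.  Introgression is implemented as routing
between existing branches rather than as explicit zero-length hybrid
branches; the two formulations are equivalent in distribution.

The coalescent core is validated distributionally: single-population TMRCA
against the Exponential(2/θ) closed form, the φ→0 and M→0 limits against
plain MSC, φ = 1 routing by construction, and two-species divergence against
msprime as an independent oracle (Kolmogorov–Smirnov at n = 10⁴).

## Sequence evolution and diploid coding

Sequences evolve under Jukes–Cantor.  Since sites are independent,
substitutions are sampled directly from the per-branch transition matrix
(change probability (3/4)(1 − e^(−4t/3)), changed base uniform over the other
three) rather than by exponential waiting times; the two schemes are
identical in distribution and the matrix route is a single vectorized pass
per branch.  The root sequence is uniform over ACGT.  Alleles 1 and 2 of the
same individual (fixed by tip labels, not re-paired at random) are merged
site-wise into IUPAC codes; only two-base ambiguities can occur.

## The beta-Markov read-depth model

Depths live in [d_min, d_max] = [2, 100] and are handled through the scaled
depth x = (d − d_min)/(d_max − d_min).  A species' average scaled depth is
x̄_s ~ beta(x̄·a_s, (1−x̄)·a_s) with a_s = 500, drawn once per dataset and
shared by all its samples, loci and sites.  Within a sequence, site 1 is
beta(x̄_s·a_p, (1−x̄_s)·a_p) with a_p = 1000, and site j is beta-distributed
with concentration a_p around p·x'_{j−1} + (1−p)·x̄_s with p = 0.9.  Emitted
depths are ⌊d + 0.5⌋.

**The chain state is the emitted integer depth**: x'_{j−1} above is the
scaled *rounded* depth of the previous site.  This is a deliberate choice.
The doublet statistics the model is fitted with (e_xy = p_x·p_xy) are defined
on integer depths, so the transition law must be a function of the integer
state; and only this variant reproduces the model's published same-depth
predictions (0.315 at mean depth 20.26 and 0.742 at 4.21; propagating the
continuous latent value instead understates both).  A consequence worth
knowing: near the lower bound the rounded chain is attracted to d_min, so at
a nominal mean depth of 3 the realized mean is ≈ 2.4 and at 4 it is ≈ 3.9;
from depth 5 upward the bias is below 1%.

The alternative "copy" model (copy the previous depth with probability p,
else a fresh beta draw) is retained for goodness-of-fit comparison; its
marginal is exactly the site-1 beta.  A gamma transition kernel is not
offered: truncating it to the depth bounds shifts the mean, which makes the
parameterization awkward.  Conditional means that touch 0 or 1 through
floating error are clamped to [10⁻⁹, 1 − 10⁻⁹].  Zero-depth sites are never
generated (d_min = 2), mirroring how zero-depth positions are masked in
variant-calling pipelines.

The chain kernel is JIT-compiled with numba and seeded from the caller's
`numpy.random.Generator`, so a 10⁷-site chain costs seconds and every track
is reproducible from the master seed.  The same-depth predictor simulates a
10⁷-site chain by default and discards a 1000-site burn-in; its Monte-Carlo
standard error is ≈ 5·10⁻⁴.

## Reads and maximum-likelihood calling

Given depth n and the true genotype, each read copies one allele (uniformly
for heterozygotes) and errs with probability ε to one of the three other
bases; a site showing more than two distinct bases is resampled wholesale
(capped at 10⁴ attempts — the cap is unreachable for ε ≤ 0.05, d ≤ 100).
Error-read base identities are retained, so a T→C read error can produce a Y
call naming the actual erroneous base.  Calling maximizes the three binomial
likelihoods over 00/01/11; allele 0 is the true base (homozygote) or first
true allele (heterozygote) when observed.  Ties — possible only at contrived
ε such as 0.5 — break toward the homozygote of the majority allele, and
toward allele 0 at an exact count tie.  The float-arithmetic decision rule is
verified against exact rational arithmetic for all n ≤ 30 and six ε values.

Allele counts k | (n, genotype class, ε) follow binomial laws (Binomial(n, ε)
for homozygotes, Binomial(n, 1/2) for heterozygotes); a Walker alias table
per (n, class, ε), built lazily and cached, samples k with one uniform draw
regardless of n.  This *two-allele* reduced model is also what the analytic
error-rate calculator describes: it enumerates k and sums the probability of
every k whose call differs from the truth.  The full per-read model deviates
from the two-allele model by O(ε) terms (third-base heterozygote calls,
resampling tilt), e.g. a heterozygote miscall probability of 0.5066 versus
0.5 at d = 2, ε = 0.01; Monte-Carlo-versus-analytic validation therefore runs
under the two-allele model, while alignment corruption uses the full model.

Two properties of the discrete ML threshold deserve emphasis, since both are
easy to get wrong in tests and interpretation: the genotyping-error rate is
not monotone in depth (at ε = 0.01 a lone error read flips the call at
d = 3–6 but is tolerated at d = 7–8, so heterozygote error is higher at d = 8
than d = 5) and not monotone in ε at fixed depth outside the study grid (at
d = 5 the homozygote rate drops from 0.049 at ε = 0.01 to 0.023 at ε = 0.05).
Consequently the right oracle for depth-mixed simulations is the analytic
rate averaged over the realized depth distribution, not a bracket.

## Error modes and the matched design

Alignment corruption always simulates reads and calls for every site; the
error mode only decides which miscalls are committed to the output (`no-err`
none, `hom-err` those at truly homozygous sites, `het-err` the converse,
`both-err` all).  Datasets generated from one seed under different modes
therefore share gene trees, true alignments, depth tracks and read draws by
construction, and the both-err committed ledger is exactly the disjoint union
of the hom-err and het-err ones.  The ledger records every miscall —
committed or suppressed — with locus, sequence, 1-based site, depth, true and
called genotype and class.  Besides the two headline classes, the astronomically
rare hom-as-other-hom and het-as-other-het outcomes of the full read model
are classified explicitly rather than folded into a neighbouring class.

## Goodness of fit

Doublet frequencies f_xy are tallied over adjacent site pairs, never across
track boundaries; empirical samtools-depth input is split at chromosome
changes and position gaps, sites below d_min dropped (which also splits the
track) and depths above d_max clipped with counts logged.  Model frequencies
e_xy are estimated from one long simulated chain (default 10⁷ sites, 1000
burn-in) because the rounded-beta chain has no tractable stationary law; the
deviation Q = Σ e_xy (e_xy − f_xy)² is then exact arithmetic on the two
tables.  The p-scan recomputes e_xy per (model, p) at the empirical mean
depth; at p = 0 the two models are the same i.i.d. process and share one
table, so their Q values coincide exactly.  Published absolute Q values for
real genomes are not reproduced here — they require the underlying read data
— but the machinery is validated by self-consistency: Q → 0 with track
length under the generating model, and the scan recovers the generating p.

## Reproducibility plumbing

A dataset's master seed is split with `numpy.random.SeedSequence` into one
stream for species mean depths and one per locus, so loci regenerate
independently.  The manifest (config, network, seed) regenerates the dataset
bit-identically, including the PHYLIP bytes.  Outputs use the BPP multilocus
PHYLIP dialect, an Imap file, FASTA per locus for the haploid truth, and the
ledger as TSV.  The heterozygote-as-ambiguity view annotates (never rewrites)
an alignment, reporting how many genotype calls a downstream
ambiguity-as-missing analysis would mask.

## Problem sizes used in the shipped checks

Exact enumerations (error decomposition, ML-caller oracle) are instantaneous.
Monte-Carlo checks use 10⁷-site chains for the same-depth predictions
(tolerance ±0.01), 10⁶-site chains for autocorrelation/mean/moment checks,
10⁵ sites per cell for the 232-cell fixed-depth calling sweep (exact central
99.7% binomial bands), 10⁴ replicates for the KS distribution tests and
5·10⁵-site tracks for the p-scan recovery.  Dataset-level tests use 3–40
loci at 120–250 sites.

## What the synthetic data do and do not show

The generator reproduces the study conditions: depth-driven genotyping
errors on MSC/MSC-I/MSC-M genealogies under JC, with species-level and
site-level depth variation.  It does not model mapping or alignment errors,
quality filters, indels, non-JC substitution processes, intra-locus
recombination, inter-locus linkage, or multi-sample genotype calling, and
depth tracks are first-order Markov whereas real coverage is more strongly
and more persistently autocorrelated (real same-depth probabilities of
0.57/0.94 exceed the model's 0.315/0.742 at the fitted p = 0.9).  Passing
tests therefore certify the implementation of this model, not the fidelity
of any real sequencing pipeline; conclusions drawn from the generated
benchmarks inherit the model's assumptions.
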