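# readcoal

Simulation of multilocus phylogenomic sequence data with realistic,
read-depth-dependent genotyping errors.

Multispecies-coalescent (MSC) methods for species-tree inference and
demographic estimation assume the input sequences are correct.  Real
genotypes, however, are called from reads, and at low read depth base-calling
errors propagate into genotyping errors — homozygotes miscalled as
heterozygotes and heterozygotes miscalled as homozygotes.  `readcoal` lets you
generate benchmark datasets in which those errors arise mechanistically, so
that the robustness of downstream MSC inference can be studied.  It is aimed
at phylogeneticists and method developers who work with unphased diploid
alignments from low-depth sequencing.

## What it simulates

For a species tree with divergence times τ and population-size parameters
θ = 4Nμ (both in expected substitutions/site), optionally with introgression
events (probability φ) or migration bands (rate M = Nm):

1. **Gene trees** per locus under the MSC / MSC-I / MSC-M structured
   coalescent (pairwise coalescent rate 2/θ; backward migration rate 4M/θ).
2. **Sequences** evolved along each gene tree under Jukes–Cantor; the two
   haploid sequences of each individual are merged into an unphased diploid
   sequence with IUPAC ambiguity codes (Y = T/C, etc.).
3. **Read depths** per site from a beta-Markov chain: the scaled depth
   x = (d − d_min)/(d_max − d_min) of site j is beta-distributed with
   concentration a_p around the mean p·x_{j−1} + (1−p)·x̄_s, where x̄_s is the
   species' average depth (itself beta with concentration a_s around the
   global mean).  Defaults: d_min = 2, d_max = 100, a_s = 500, a_p = 1000,
   p = 0.9.
4. **Reads and genotype calls**: at a site of depth n, each read copies one
   allele and errs with probability ε to a uniform alternative base (sites
   with three or more distinct bases are resampled).  The genotype maximizes
   the binomial likelihoods

       L(00|k) = C(n,k) (1−ε)^(n−k) ε^k
       L(01|k) = C(n,k) (1/2)^n
       L(11|k) = C(n,k) (1−ε)^k ε^(n−k)

   over genotypes 00/01/11, where k of the n reads carry the alternative
   allele.

An error-mode switch (`no-err` / `hom-err` / `het-err` / `both-err`) commits
only the selected class of miscalls, with matched reads across modes from one
seed, so each error type can be studied in isolation.  The package also
provides the exact genotyping-error calculator (enumeration over k) and
goodness-of-fit machinery for depth models: doublet frequencies f_xy,
transition matrices p_xy, model frequencies e_xy = p_x·p_xy, and the
deviation Q = Σ e_xy (e_xy − f_xy)².

## Worked example

```python
import numpy as np
import readcoal as rc

# exact genotyping-error rates at depth 5, base-calling error 1%
rc.analytic_error_rate("homozygote", 5, 0.01)    # 0.0490099501
rc.analytic_error_rate("heterozygote", 5, 0.01)  # 0.0625

# a 40-locus dataset on the balanced 5-species tree, theta = 0.01
cfg = rc.SimulationConfig(loci=40, samples_per_species=1, sites=250,
                          error_rate=0.01, mean_depth=5.0, seed=1,
                          error_mode="both-err")
net = rc.build_preset("B", 0.01)
ds = rc.simulate_dataset(cfg, net)
print(rc.report_error_rates([ds]).to_string(index=False))
```

```
 mean_depth  error_rate genotype_class  n_sites  n_miscalled  observed_rate    mc_se  analytic_at_mean_depth
        5.0        0.01     homozygote    49468         1877       0.037944 0.000859                 0.04901
        5.0        0.01   heterozygote      532           80       0.150376 0.015497                 0.06250
```

The homozygote row says: of 49,468 truly homozygous genotype sites, 3.79%
were miscalled (almost all as spurious heterozygotes).  That is below the
fixed-depth analytic value 4.90% because realized depths vary around the
mean of 5 and the error rate is a non-monotone, on-average-lower function of
the realized depth.  Multiplying by the genotype frequencies (heterozygosity
≈ θ = 0.01) shows hom-err errors outnumber het-err errors by almost two
orders of magnitude in the data — the error class that drives biases in
downstream coalescent inference.

The same machinery is available from the shell:

```bash
readcoal simulate --config config.yaml --out-dir out/   # PHYLIP + Imap + ledger
readcoal error-rates --depth 3,5,8 --eps 0,0.001,0.01
readcoal predict-same-depth --mean-depth 4.21 --seed 1
readcoal gof --depths depths.tsv --out-dir gof/         # Q over a grid of p
```

`simulate` writes a BPP-dialect multilocus PHYLIP alignment (sequence names
`individual^species`, heterozygotes as IUPAC codes), an Imap file, an error
ledger TSV (every miscall with site, depth, class and commit status) and a
manifest from which the dataset can be regenerated bit-identically.

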