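# Methods

## The problem

SNP genotyping arrays carry only variants that were discovered — and common —
in a finite, non-random discovery panel. Statistics computed from array
genotypes therefore over-represent common variation: expected heterozygosity
(H_E) is inflated, most strongly for the populations that contributed to SNP
discovery, and allele-frequency-based distances between discovery and
non-discovery populations are distorted. `ascbias` implements a fully
self-contained in-silico version of this situation with known truth, plus the
mitigation strategy of imputing the array back up to full resolution from a
small, fully observed reference panel.

## Synthetic data model

Populations diverge from a common ancestor under pure drift:

* Ancestral allele frequencies are Uniform(0.05, 0.95) by default, so the
  global site-frequency spectrum is dominated by common variants, as on the
  source data of a real array. The range is configurable to include rare
  variants.
* Population frequencies follow the Balding–Nichols model: a Beta
  distribution with mean p (the ancestral frequency) and variance F·p(1−p),
  where F ∈ [0, 1) is a per-population drift parameter. F = 0 reproduces the
  ancestral frequencies exactly. For two populations with equal drift F the
  expected pairwise ratio-of-sums F_ST is F/(2−F) (not F): with
  E[H̄S] = 2p(1−p)(1−F) and E[HT] = p(1−p)(2−F) per locus, the ratio of the
  summed numerator and denominator converges to F/(2−F). The tests use this
  analytic expectation.
* Haplotypes are founder mosaics: per population, `n_founder_haplotypes`
  (default 10) founders are drawn site-wise Bernoulli from the population
  frequencies; each sampled haplotype copies one founder and switches
  template between adjacent sites with probability 1 − exp(−λ·d) for genetic
  distance d cM (λ = `mosaic_switch_rate`, default 1 per cM). This creates
  block-wise LD and realistic haplotype sharing without a full coalescent
  simulation. Ten founders per population is in the range of the effective
  haplotype diversity of managed livestock populations; smaller values give
  longer shared tracts and easier imputation.
* Pooled sequencing draws `n_pool` haplotypes without replacement, a
  Poisson(mean depth) read depth per site and Binomial(depth, pool fraction)
  alternate reads. Sequencing errors are not modelled: the pooling bias of
  interest is driven by finite pool size and finite coverage, not by read
  errors.

All randomness derives from one master seed through `numpy` `SeedSequence`
spawn keys (frequencies, founders and mosaics per population get fixed
keys), so identical model + seed gives bit-identical output. Scenario cells
get child seeds from a SHA-256 hash of (master seed, cell identifiers),
keeping every cell independently reproducible and all seeds below 2^31.

## Array ascertainment

An in-silico array is the set of sites with minor-allele frequency strictly
greater than a threshold (default 0.05) *within the discovery population*,
computed from non-missing genotype calls. Masked sites are set to missing
for every study individual rather than deleted, so they remain addressable
imputation targets. The LD-pruning comparison arm removes, in sliding
windows (50 SNPs, step 5 by default), the site with the highest variance
inflation factor until all VIFs are ≤ 2; exact collinearity is treated as
infinite VIF, ties remove the lowest site index, and missing dosages are
mean-imputed for the correlation computations only.

## Reference panels

Five strategies: `allPop` (k per population, balanced), `randSamp` (m
individuals at random), `randPop`/`minPop`/`maxPop` (5 individuals from each
of q random / closest / most distant populations, by Nei's distance to the
discovery population, computed from the full pre-ascertainment genotypes).
The discovery population is itself eligible for selection; distance ties
break by population label. After selection, reference sites are those with
MAF > 0.01 (strict) within the panel — only these can be imputed.

## Imputation

A haploid Li–Stephens copying model replaces the external imputation tool:
the hidden state is which reference haplotype is copied; between adjacent
sites at distance d cM the switch probability is
ρ = 1 − exp(−0.04·ne·d/K) with K reference haplotypes and ne the effective
population size (default 1000, a common setting for livestock); chromosome
boundaries use ρ = 1. Emissions are 1−ε on allele match and ε on mismatch
(ε default 1e-4), uniform at untyped sites. Forward–backward posteriors over
states give per-site allele posteriors (Σ_k γ_k·allele_k); an individual's
expected dosage is the sum of its two haplotype posteriors, and the
best-guess genotype is the dosage rounded half-to-even. Typed genotypes pass
through unchanged, always. With no typed site in a window the posterior
falls back to the reference allele frequencies (flat state posterior).

Long maps are processed in windows of 200 cM with 10% overlap; each site
takes its posterior from the window whose centre is nearest. Phasing is
assumed known (the simulation emits truth haplotypes); this is the largest
fidelity gap relative to a real imputation run, which must phase first.

Per-site quality is DR2, the estimated squared correlation between imputed
and true allele dose, operationalised as
Var_h(p_h) / (Var_h(p_h) + mean_h(p_h(1−p_h))) over the posterior allele
probabilities of all study haplotypes, clamped to [0, 1] and undefined when
the denominator is 0. At typed sites the pass-through posteriors are 0/1, so
DR2 is 1 wherever both alleles occur.

The forward–backward kernel is numba-compiled and verified against
exhaustive enumeration over all K^S copy paths on instances with ≤ 4 sites
and ≤ 3 reference haplotypes (tolerance 1e-10).

## Estimators

* H_E = mean over loci of 2p(1−p); H_O = proportion of heterozygous calls
  among all non-missing calls (identical to loci-then-individuals averaging
  on complete data).
* Pool-seq H_E is multiplied by n/(n−1) (n = haplotypes in the pool). This
  removes the finite-pool component of the downward bias exactly; the
  finite-coverage component, E[1 − 1/d | d > 0], remains and vanishes only
  at high depth. At Poisson(30) depth it is ≈ 0.966, so the corrected
  estimator is unbiased only in the high-depth limit; the tests check both
  regimes against the analytic factors.
* Nei's standard distance D = −ln(Σ x·y / √(Σ x²·Σ y²)) with the inner sums
  over both alleles per biallelic locus and the outer sums over loci.
  Disjoint allele sets give +inf (a representable value, dropped with a
  count in downstream regressions).
* Pairwise F_ST is the ratio-of-sums G_ST form, Σ(HT−H̄S)/ΣHT, with HT from
  the unweighted mean of the two population frequencies.

## Bias quantification

Populations are grouped per scenario cell as discovery / reference /
application (discovery takes precedence; when every population has reference
individuals the reference label is uninformative and non-discovery
populations are all "application"). Biased estimates are regressed on true
ones per group by OLS — mathematically identical to a single model with
group-specific intercepts and slopes — together with the within-group
Pearson correlation and the mean relative overestimation
mean_j((biased_j − true_j)/true_j). Groups with fewer than 3 finite pairs
or constant truth are flagged unreliable. Per-animal imputation accuracy is
the Pearson r between true and imputed dosages at imputed sites only
(including typed sites would inflate it trivially). Leave-one-out validation
removes each panel member in turn, re-applies the reference-site filter,
imputes the member from its array sites, and records whether a
same-population proxy remained — the mechanism behind downward-biased
accuracy for populations with a single reference sample.

## Study conditions used by the tests and the acceptance script

One replicate simulates 10 populations × 20 individuals × 5,000 SNPs on a
100 cM map, with per-population drift evenly spaced on [0.05, 0.25]
(mean 0.15). The spread matters: with identical drift for every population
the between-population variance of true H_E at this locus count is ~0.5% of
its mean, and a regression of biased on true H_E would be fit to pure noise.
A panel mixing low-diversity (commercial-like) and high-diversity
(wild-like) populations reproduces the empirically relevant situation.
Every population serves once as the discovery population; reference panels
are a balanced one-per-population panel (10 individuals) and an unbalanced
panel of 5 individuals from each of the 2 populations most distant from
discovery (also 10). The acceptance tests run 30 such replicates, the
acceptance script 10; these sizes give stable paired tests while keeping a
replicate at ~15 s on one CPU.

Observed patterns at these conditions: ascertained H_E overestimation
~0.35 (discovery) vs ~0.09 (application); application-group slope ~1.09;
after balanced-panel imputation the discovery overestimation roughly halves
and within-group correlations rise above 0.99, while median per-animal
accuracy is ~0.86 (discovery) vs ~0.71 (application). The internal HMM's
accuracy is deliberately not tuned to match an external tool; because it is
below what a production imputation tool achieves on real data, imputed
per-population frequencies are somewhat shrunk toward the panel mean, which
compresses the application-group slope below 1. Consequences of this
shrinkage are discussed in the limitations.

## Numerical choices

* Strict ">" at both MAF thresholds (0.05 discovery, 0.01 reference).
* MAF and allele frequencies use non-missing calls only; all-missing sites
  are undefined (NaN) and excluded from masks and filters.
* Best-guess rounding of dosages 0.5/1.5 is half-to-even.
* Non-finite estimator values (D = +inf) are dropped pairwise in
  regressions, with the count reported.
* State posteriors are normalised per site; the dense diagnostic
  implementation guarantees row sums of 1 to 1e-9.
* VIF pruning falls back from matrix inversion to per-site least squares
  when a window's correlation matrix is (near-)singular.

## Known limitations

* Founder-mosaic LD is blockier than coalescent LD; rare variants are absent
  by default; there is no mutation, selection or gene flow.
* Phasing is assumed; genotyping error is not modelled.
* The internal imputer is a plain haploid Li–Stephens HMM without the state-
  space reductions or iterative refinements of production tools, so absolute
  accuracies are lower than published values on real data; comparisons
  between panel designs remain meaningful because all arms share the engine.
* With a single small discovery population, retained sites are systematically
  less differentiated, so F_ST is attenuated under ascertainment more than
  Nei's D is inflated — the opposite ordering of the robustness observed
  when arrays come from large multi-population discovery panels.
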