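# ascbias

Simulation and mitigation of **SNP ascertainment bias** in population-genetic
studies, with genotype imputation as the correction strategy.

Genotyping arrays only contain SNPs that were discovered — and common — in a
finite discovery panel. Estimates computed from array genotypes therefore
systematically over-represent common variation: expected heterozygosity
(H_E) and observed heterozygosity (H_O) are inflated, most strongly for the
populations used for SNP discovery, and frequency-based distances (Nei's D,
F_ST) between discovery and non-discovery populations are distorted. One
practical mitigation is to impute the array data up to full resolution from
a small panel of fully sequenced reference individuals — which works well
when the panel covers the study populations evenly, and can introduce a new
bias toward the reference populations when it does not.

`ascbias` implements the complete in-silico study of this phenomenon for
researchers in conservation and livestock genetics who want to quantify or
correct the bias in their own designs:

* **synthetic data** with known truth — multi-population genotypes under a
  Balding–Nichols drift model (population frequency ~ Beta with mean p and
  variance F·p(1−p)), founder-mosaic haplotypes with LD on a genetic map,
  and a pooled-sequencing emulator with finite-pool and finite-coverage
  noise;
* **array ascertainment** by discovery-population MAF filtering
  (MAF > 0.05, strict) and an LD-pruning comparison arm (sliding-window VIF);
* **reference panels** under five sampling strategies (`allPop`,
  `randSamp`, `randPop`, `minPop`, `maxPop`) with a reference-side
  MAF > 0.01 filter;
* **imputation** with a haploid Li–Stephens haplotype-copying HMM
  (switch probability ρ = 1 − exp(−0.04·ne·d/K), forward–backward allele
  posteriors, expected dosages, best-guess genotypes and per-site DR2);
* **estimators**: H_E = Σ_l 2p_l(1−p_l)/L, H_O, the Futschik–Schlötterer
  n/(n−1) pool-seq correction, Nei's standard distance
  D = −ln(Σxy/√(Σx²·Σy²)) and ratio-of-sums F_ST = Σ(HT−H̄S)/ΣHT;
* **evaluation**: group-specific regression of biased on true estimates
  (unbiased data lies on the line of identity), mean relative
  overestimation, within-group correlation, per-animal Pearson accuracy and
  leave-one-out panel validation.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
import ascbias as ab

# 10 populations x 20 individuals x 5,000 SNPs on a 100 cM map;
# drift spread over [0.05, 0.25] mixes low- and high-diversity populations
cfg = ab.default_study_config(seed=11)
result = ab.run_scenario(cfg)

report = ab.pooled_regression(
    result.per_population.query("strategy == 'allPop'"), "he_ascertained")
print(report.table[["group", "n", "slope", "r", "mean_overestimation"]])
```

```
         group   n     slope         r  mean_overestimation
0    discovery  10  0.118037  0.819871             0.360679
1  application  90  1.087103  0.992460             0.087573
```

Ascertained H_E overestimates the truth by 36% for the populations the
arrays were designed in, versus 9% for the others; the application-group
slope of 1.09 (> 1) shows the inflation grows with a population's true
diversity. After imputation with a balanced one-individual-per-population
reference panel (`"he_imputed"` in the same call), the discovery
overestimation roughly halves and the within-group correlations rise above
0.99:

```
         group   n     slope         r  mean_overestimation
0    discovery  10  0.486582  0.994856             0.190605
1  application  90  0.895378  0.997095             0.022281
```

Per-animal imputation accuracy is higher for discovery-population
individuals (their array is tailored to their variation):

```python
print(result.accuracy.query("strategy == 'allPop'")
      .groupby("group")["r"].median())
```

```
group
application    0.711540
discovery      0.860206
```

The same pipeline is scriptable from the shell (`ascbias simulate`,
`ascertain`, `sample-ref`, `impute`, `estimate`, `run-scenario`), reading
and writing VCF, PLINK-style maps and TSV tables, so any synthetic stage can
be replaced by real data or an externally imputed VCF.

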