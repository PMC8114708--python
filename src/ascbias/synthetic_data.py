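"""Synthetic multi-population genotype data with known truth.

The generator stands in for a real multi-population genotype panel: many
populations diverged from a common ancestor, SNPs on a genetic map with
linkage disequilibrium, and (optionally) pooled-sequencing allele-frequency
estimates with finite-pool and finite-coverage noise.

Model
-----
* Ancestral allele frequencies are drawn uniformly from a configurable range.
* Each population's frequency is drawn from a Balding–Nichols (beta)
  distribution with mean equal to the ancestral frequency and variance
  ``F p (1-p)`` controlled by a per-population drift parameter ``F``.
* Per population, a small set of founder haplotypes is drawn site-wise
  Bernoulli from the population frequencies; sampled haplotypes are mosaics
  of the founders with template switches occurring at a Poisson rate per cM,
  which creates LD and makes haplotype-copying imputation non-trivial.
* Pooled sequencing draws a finite pool of haplotypes without replacement,
  a Poisson read depth per site, and binomial read counts, so the resulting
  frequency estimates carry both pool-size and coverage noise.

All randomness derives deterministically from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationModel",
    "GeneticMap",
    "HaplotypePanel",
    "GenotypeMatrix",
    "PoolSeqEstimate",
    "simulate_population_frequencies",
    "simulate_haplotypes",
    "simulate_pool_seq",
    "simulate_dataset",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for (master seed, spawn key)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PopulationModel:
    """Parameters of the multi-population simulation.

    Attributes
    ----------
    n_populations
        Number of populations diverged from the common ancestor.
    drift_F
        Per-population differentiation parameter in [0, 1); a scalar is
        broadcast to all populations. ``F = 0`` means the population
        frequencies equal the ancestral frequencies exactly.
    ancestral_freq_range
        Interval strictly inside (0, 1) from which ancestral frequencies are
        drawn uniformly. The default keeps the global site-frequency spectrum
        dominated by common variants, as on a genotyping array's source data.
    n_sites
        Number of biallelic SNPs.
    n_founder_haplotypes
        Founder haplotypes per population; smaller values mean longer shared
        haplotype tracts (stronger LD).
    mosaic_switch_rate
        Expected copy-template switches per cM when sampling haplotypes as
        founder mosaics; 0 disables recombination entirely.
    seed
        Master seed; all child streams derive from it deterministically.
    """

    n_populations: int = 10
    drift_F: float | Sequence[float] = 0.15
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    n_sites: int = 5000
    n_founder_haplotypes: int = 10
    mosaic_switch_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        f = np.atleast_1d(np.asarray(self.drift_F, dtype=float))
        if f.size == 1:
            f = np.repeat(f, self.n_populations)
        if f.size != self.n_populations:
            raise ValueError("drift_F must be scalar or one value per population")
        if np.any((f < 0) | (f >= 1)):
            raise ValueError("drift_F values must lie in [0, 1)")
        self._drift = f
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must be strictly inside (0, 1)")
        if self.n_founder_haplotypes < 1:
            raise ValueError("n_founder_haplotypes must be >= 1")
        if self.mosaic_switch_rate < 0:
            raise ValueError("mosaic_switch_rate must be >= 0")

    @property
    def drift(self) -> np.ndarray:
        return self._drift

    @property
    def population_labels(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_populations)]


@dataclass
class GeneticMap:
    """Per-site chromosome, physical (bp, 1-based) and genetic (cM) position.

    Within a chromosome bp must be strictly increasing and cM non-decreasing.
    """

    chrom: np.ndarray
    bp: np.ndarray
    cm: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=float)
        if not (self.chrom.shape == self.bp.shape == self.cm.shape):
            raise ValueError("chrom, bp and cm must have the same length")
        if self.ids is None:
            self.ids = np.array([f"{c}_{p}" for c, p in zip(self.chrom, self.bp)],
                                dtype=object)
        else:
            self.ids = np.asarray(self.ids, dtype=object)
            if self.ids.shape != self.bp.shape:
                raise ValueError("ids must match the number of sites")
        for c in pd.unique(self.chrom):
            sel = self.chrom == c
            if np.any(np.diff(self.bp[sel]) <= 0):
                raise ValueError(f"bp not strictly increasing on chromosome {c}")
            if np.any(np.diff(self.cm[sel]) < 0):
                raise ValueError(f"cM decreasing on chromosome {c}")

    @property
    def n_sites(self) -> int:
        return self.bp.size

    def subset(self, idx) -> "GeneticMap":
        idx = np.asarray(idx)
        return GeneticMap(self.chrom[idx], self.bp[idx], self.cm[idx],
                          self.ids[idx])

    def global_cm(self) -> np.ndarray:
        """cM positions made globally non-decreasing across chromosomes.

        Chromosome boundaries receive a large offset; the imputation layer
        additionally forces a free-recombination transition there.
        """
        out = self.cm.astype(float).copy()
        offset = 0.0
        prev_chrom = None
        prev_end = 0.0
        for i in range(out.size):
            if self.chrom[i] != prev_chrom:
                if prev_chrom is not None:
                    offset = prev_end - out[i] + 1000.0
                prev_chrom = self.chrom[i]
            out[i] += offset
            prev_end = out[i]
        return out

    @classmethod
    def uniform(cls, n_sites: int, span_cm: float = 100.0, chrom: str = "1",
                bp_start: int = 1, bp_step: int = 1000) -> "GeneticMap":
        """Evenly spaced map on one chromosome spanning ``span_cm``."""
        bp = bp_start + bp_step * np.arange(n_sites, dtype=np.int64)
        cm = np.linspace(0.0, span_cm, n_sites) if n_sites > 1 else np.array([0.0])
        return cls(np.repeat(chrom, n_sites), bp, cm)


@dataclass
class HaplotypePanel:
    """Phased alleles (sites x haplotypes); haplotypes 2i, 2i+1 belong to
    individual i. Alleles are 0/1, -1 for missing."""

    alleles: np.ndarray
    samples: np.ndarray
    populations: np.ndarray
    gmap: GeneticMap

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.samples = np.asarray(self.samples, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.alleles.shape[1] % 2:
            raise ValueError("haplotype count must be even (2 per individual)")
        if self.alleles.shape[1] != 2 * self.samples.size:
            raise ValueError("need exactly two haplotypes per individual")
        if self.populations.size != self.samples.size:
            raise ValueError("one population label per individual required")
        if self.populations.size == 0:
            raise ValueError("panel must contain at least one individual")
        if self.alleles.shape[0] != self.gmap.n_sites:
            raise ValueError("allele matrix does not match the genetic map")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.samples.size

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    def haplotype_populations(self) -> np.ndarray:
        return np.repeat(self.populations, 2)

    def individuals_of(self, population: str) -> np.ndarray:
        return np.flatnonzero(self.populations == population)

    def subset_individuals(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        hap_idx = np.empty(2 * idx.size, dtype=np.intp)
        hap_idx[0::2] = 2 * idx
        hap_idx[1::2] = 2 * idx + 1
        return HaplotypePanel(self.alleles[:, hap_idx], self.samples[idx],
                              self.populations[idx], self.gmap)

    def subset_sites(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(self.alleles[idx], self.samples,
                              self.populations, self.gmap.subset(idx))

    def to_genotypes(self) -> "GenotypeMatrix":
        a, b = self.alleles[:, 0::2], self.alleles[:, 1::2]
        dos = (a + b).astype(np.int8)
        dos[(a < 0) | (b < 0)] = -1
        return GenotypeMatrix(dos, self.samples.copy(), self.populations.copy(),
                              self.gmap)

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(self.alleles.copy(), self.samples.copy(),
                              self.populations.copy(), self.gmap)


@dataclass
class GenotypeMatrix:
    """0/1/2-coded dosage matrix (sites x individuals), -1 for missing."""

    dosages: np.ndarray
    samples: np.ndarray
    populations: np.ndarray
    gmap: GeneticMap

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.samples = np.asarray(self.samples, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        if not np.isin(self.dosages, (-1, 0, 1, 2)).all():
            raise ValueError("dosages must be 0/1/2 or -1 (missing)")
        if self.dosages.shape[1] != self.samples.size:
            raise ValueError("dosage matrix does not match sample list")
        if self.populations.size != self.samples.size:
            raise ValueError("one population label per individual required")
        if self.dosages.shape[0] != self.gmap.n_sites:
            raise ValueError("dosage matrix does not match the genetic map")

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.samples.size

    @property
    def population_labels(self) -> list[str]:
        return list(pd.unique(self.populations))

    def individuals_of(self, population: str) -> np.ndarray:
        return np.flatnonzero(self.populations == population)

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosages[:, idx], self.samples[idx],
                              self.populations[idx], self.gmap)

    def subset_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosages[idx], self.samples,
                              self.populations, self.gmap.subset(idx))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), self.samples.copy(),
                              self.populations.copy(), self.gmap)


@dataclass
class PoolSeqEstimate:
    """Pool-seq allele-frequency estimates for one population.

    ``freq`` is reads/depth per site (NaN where depth is 0);
    ``n_haplotypes`` is the *n* of the ``n/(n-1)`` correction factor.
    """

    freq: np.ndarray
    depth: np.ndarray
    n_haplotypes: int
    population: str | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.n_haplotypes < 2:
            raise ValueError("pool must contain at least 2 haplotypes")
        finite = self.freq[np.isfinite(self.freq)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("frequency estimates must lie in [0, 1]")
        if np.any(np.isnan(self.freq) != (self.depth == 0)):
            raise ValueError("estimates must be missing exactly where depth is 0")


# ---------------------------------------------------------------------------
# simulation operations
# ---------------------------------------------------------------------------

def simulate_population_frequencies(model: PopulationModel) -> pd.DataFrame:
    """Draw true per-population allele frequencies.

    Ancestral frequencies are Uniform(ancestral_freq_range); each population's
    frequencies follow Balding–Nichols: Beta with mean p and variance
    ``F p (1-p)``, i.e. shape parameters ``p (1-F)/F`` and ``(1-p)(1-F)/F``.
    ``F = 0`` copies the ancestral frequencies exactly.

    Returns a DataFrame with one row per population (index = population
    labels) and one column per site.
    """
    rng = _rng(model.seed, 0)
    anc = rng.uniform(*model.ancestral_freq_range, size=model.n_sites)
    rows = np.empty((model.n_populations, model.n_sites))
    for i, f in enumerate(model.drift):
        if f == 0.0:
            rows[i] = anc
        else:
            c = (1.0 - f) / f
            rows[i] = rng.beta(anc * c, (1.0 - anc) * c)
    df = pd.DataFrame(rows, index=model.population_labels,
                      columns=np.arange(model.n_sites))
    df.attrs["ancestral"] = anc
    return df


def _mosaic_indices(rng: np.random.Generator, n_haplotypes: int,
                    switch_prob: np.ndarray, n_founders: int) -> np.ndarray:
    """Founder index per (haplotype, site) for founder-mosaic copying."""
    n_sites = switch_prob.size + 1
    start = rng.integers(0, n_founders, size=(n_haplotypes, 1))
    if n_sites == 1 or n_founders == 1:
        return np.broadcast_to(start, (n_haplotypes, n_sites)).copy()
    switch = rng.random((n_haplotypes, n_sites - 1)) < switch_prob
    candidates = rng.integers(0, n_founders, size=(n_haplotypes, n_sites))
    candidates[:, 0] = start[:, 0]
    change = np.concatenate(
        [np.ones((n_haplotypes, 1), dtype=bool), switch], axis=1)
    # forward-fill the founder chosen at the latest switch point
    pos = np.where(change, np.arange(n_sites)[None, :], 0)
    pos = np.maximum.accumulate(pos, axis=1)
    return candidates[np.arange(n_haplotypes)[:, None], pos]


def simulate_haplotypes(freqs: pd.DataFrame,
                        n_individuals_per_pop: int | Mapping[str, int],
                        gmap: GeneticMap, model: PopulationModel
                        ) -> HaplotypePanel:
    """Sample phased haplotypes as founder mosaics.

    Per population, ``n_founder_haplotypes`` founders are drawn site-wise
    Bernoulli from the population frequencies; each sampled haplotype copies
    one founder and switches template with probability
    ``1 - exp(-mosaic_switch_rate * d_cM)`` per adjacent-site interval
    (probability 1 across chromosome boundaries), which creates realistic
    block-wise LD. Deterministic given the model seed.
    """
    if freqs.shape[1] != gmap.n_sites:
        raise ValueError("frequency table does not cover all map sites")
    pops = list(freqs.index)
    if isinstance(n_individuals_per_pop, int):
        counts = {p: n_individuals_per_pop for p in pops}
    else:
        counts = dict(n_individuals_per_pop)
    g = gmap.global_cm()
    d = np.diff(g)
    switch_prob = 1.0 - np.exp(-model.mosaic_switch_rate * d)
    new_chrom = gmap.chrom[1:] != gmap.chrom[:-1]
    switch_prob[new_chrom] = 1.0

    blocks, samples, labels = [], [], []
    for i, pop in enumerate(pops):
        n_ind = counts[pop]
        if n_ind < 1:
            continue
        founder_rng = _rng(model.seed, 1, i)
        founders = (founder_rng.random((gmap.n_sites, model.n_founder_haplotypes))
                    < freqs.loc[pop].to_numpy()[:, None]).astype(np.int8)
        mosaic_rng = _rng(model.seed, 2, i)
        idx = _mosaic_indices(mosaic_rng, 2 * n_ind, switch_prob,
                              model.n_founder_haplotypes)
        alleles = founders[np.arange(gmap.n_sites)[None, :], idx].T
        blocks.append(alleles.astype(np.int8))
        samples.extend(f"{pop}_i{j + 1}" for j in range(n_ind))
        labels.extend([pop] * n_ind)
    if not blocks:
        raise ValueError("no individuals requested")
    return HaplotypePanel(np.concatenate(blocks, axis=1),
                          np.array(samples, dtype=object),
                          np.array(labels, dtype=object), gmap)


def simulate_pool_seq(haplotypes: HaplotypePanel, n_pool: int,
                      mean_depth: float, seed: int,
                      population: str | None = None) -> PoolSeqEstimate:
    """Emulate pooled sequencing of one population.

    ``n_pool`` haplotypes are drawn without replacement from the population;
    per site, read depth is Poisson(mean_depth) and alternate-read counts are
    Binomial(depth, pool allele fraction). The estimate is reads/depth;
    zero-depth sites are missing.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    panel = haplotypes
    if population is not None:
        panel = haplotypes.subset_individuals(haplotypes.individuals_of(population))
    else:
        pops = pd.unique(panel.populations)
        if len(pops) != 1:
            raise ValueError("panel spans multiple populations; pass `population`")
        population = pops[0]
    if n_pool > panel.n_haplotypes:
        raise ValueError(f"pool size {n_pool} exceeds available haplotypes "
                         f"({panel.n_haplotypes})")
    rng = np.random.default_rng(seed)
    cols = rng.choice(panel.n_haplotypes, size=n_pool, replace=False)
    pool_frac = panel.alleles[:, cols].mean(axis=1)
    depth = rng.poisson(mean_depth, size=panel.n_sites)
    reads = rng.binomial(depth, pool_frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(depth > 0, reads / np.maximum(depth, 1), np.nan)
    return PoolSeqEstimate(freq, depth, n_pool, population)


@dataclass
class SimulatedDataset:
    """Truth bundle: frequencies, map, phased haplotypes and genotypes."""

    model: PopulationModel
    freqs: pd.DataFrame
    gmap: GeneticMap
    haplotypes: HaplotypePanel
    genotypes: GenotypeMatrix


def simulate_dataset(model: PopulationModel,
                     n_individuals_per_pop: int | Mapping[str, int] = 20,
                     gmap: GeneticMap | None = None,
                     span_cm: float = 100.0) -> SimulatedDataset:
    """Convenience wrapper: frequencies -> haplotypes -> genotypes."""
    if gmap is None:
        gmap = GeneticMap.uniform(model.n_sites, span_cm=span_cm)
    freqs = simulate_population_frequencies(model)
    haps = simulate_haplotypes(freqs, n_individuals_per_pop, gmap, model)
    return SimulatedDataset(model, freqs, gmap, haps, haps.to_genotypes())
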