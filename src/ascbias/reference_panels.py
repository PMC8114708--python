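"""Reference-panel construction for imputation.

Five sampling strategies select the fully observed individuals that form the
imputation reference set:

* ``allPop``   — k individuals from every population (balanced).
* ``randSamp`` — m individuals uniformly at random from the whole study set.
* ``randPop``  — 5 individuals from each of q randomly chosen populations.
* ``minPop``   — 5 individuals from each of the q populations closest to the
  discovery population by Nei's distance.
* ``maxPop``   — as minPop but the q most distant populations.

After selection, reference sites are restricted to those with MAF > 0.01
(strict) within the selected individuals; only these sites can be imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import estimators
from .ascertainment import compute_maf
from .synthetic_data import GenotypeMatrix

__all__ = [
    "STRATEGIES",
    "ReferencePanel",
    "sample_reference",
    "filter_reference_sites",
    "population_distance_matrix",
]

STRATEGIES = ("allPop", "randSamp", "randPop", "minPop", "maxPop")


@dataclass
class ReferencePanel:
    """A selected reference set: individual indices plus provenance."""

    individuals: np.ndarray          # indices into the source genotype matrix
    samples: np.ndarray              # sample ids of the selected individuals
    populations: np.ndarray          # population label per selected individual
    strategy: str
    params: dict
    seed: int
    sites: np.ndarray | None = None  # retained reference sites (post MAF filter)
    maf_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; "
                             f"expected one of {STRATEGIES}")
        self.individuals = np.asarray(self.individuals, dtype=np.intp)

    @property
    def n_individuals(self) -> int:
        return self.individuals.size

    def population_counts(self) -> pd.Series:
        return pd.Series(self.populations).value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "individual": self.samples, "population": self.populations,
            "strategy": self.strategy, "seed": self.seed})


def _take(rng: np.random.Generator, pool: np.ndarray, k: int,
          what: str) -> np.ndarray:
    if k > pool.size:
        raise ValueError(f"requested {k} individuals but {what} holds {pool.size}")
    return np.sort(rng.choice(pool, size=k, replace=False))


def _ranked_populations(distances: pd.DataFrame, discovery_pop: str,
                        largest: bool) -> list[str]:
    """Populations ordered by distance to the discovery population.

    Ties are broken by population-label order for reproducibility.
    """
    row = distances.loc[discovery_pop]
    items = sorted(((float(row[p]), str(p)) for p in distances.columns),
                   key=lambda t: (-t[0] if largest else t[0], t[1]))
    return [p for _, p in items]


def sample_reference(strategy: str, params: dict, genotypes: GenotypeMatrix,
                     discovery_pop: str | None = None,
                     distances: pd.DataFrame | None = None,
                     seed: int = 0) -> ReferencePanel:
    """Select reference individuals under one of the five strategies.

    Parameters per strategy: ``allPop`` takes ``k`` (individuals per
    population); ``randSamp`` takes ``m`` (total individuals); ``randPop``,
    ``minPop`` and ``maxPop`` take ``q`` (number of populations) and
    optionally ``per_pop`` (default 5).  ``minPop``/``maxPop`` additionally
    require a square population distance matrix (e.g. Nei's D).  Sampling
    within populations is uniform without replacement and deterministic for
    a given seed.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    pops = genotypes.population_labels

    if strategy == "allPop":
        k = int(params["k"])
        chosen = [_take(rng, genotypes.individuals_of(p), k, f"population {p}")
                  for p in pops]
        idx = np.concatenate(chosen)
    elif strategy == "randSamp":
        m = int(params["m"])
        idx = _take(rng, np.arange(genotypes.n_individuals), m, "the study set")
    else:
        q = int(params["q"])
        per_pop = int(params.get("per_pop", 5))
        if strategy == "randPop":
            if q > len(pops):
                raise ValueError(f"requested {q} populations but only "
                                 f"{len(pops)} exist")
            sel_pops = sorted(rng.choice(np.asarray(pops, dtype=object),
                                         size=q, replace=False))
        else:
            if distances is None:
                raise ValueError(f"{strategy} requires a population distance matrix")
            if discovery_pop is None:
                raise ValueError(f"{strategy} requires a discovery population")
            ranked = _ranked_populations(distances, discovery_pop,
                                         largest=(strategy == "maxPop"))
            sel_pops = ranked[:q]
        chosen = [_take(rng, genotypes.individuals_of(p), per_pop,
                        f"population {p}") for p in sel_pops]
        idx = np.concatenate(chosen)

    idx = np.sort(idx)
    return ReferencePanel(idx, genotypes.samples[idx],
                          genotypes.populations[idx], strategy, dict(params),
                          seed)


def filter_reference_sites(genotypes: GenotypeMatrix, panel: ReferencePanel,
                           maf_threshold: float = 0.01) -> ReferencePanel:
    """Restrict the panel's site set to MAF > threshold within its members.

    These are the only sites imputation can output as non-missing targets.
    """
    maf = compute_maf(genotypes, individuals=panel.individuals)
    with np.errstate(invalid="ignore"):
        keep = (maf > maf_threshold) & np.isfinite(maf)
    return replace(panel, sites=np.flatnonzero(keep),
                   maf_threshold=maf_threshold)


def population_distance_matrix(genotypes: GenotypeMatrix,
                               statistic: str = "nei") -> pd.DataFrame:
    """Square symmetric matrix of pairwise Nei's D (or F_ST) from genotypes."""
    pops = genotypes.population_labels
    freqs = {p: estimators.PopulationFrequencies.from_genotypes(genotypes, p)
             for p in pops}
    fn = estimators.nei_distance if statistic == "nei" else estimators.fst_pairwise
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            d = fn(freqs[a], freqs[b])
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat
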