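"""Population-genetic estimators used throughout the pipeline.

All statistics operate on per-locus allele frequencies of biallelic loci:

* expected heterozygosity  ``H_E = mean_l 2 p_l (1 - p_l)``
* observed heterozygosity  ``H_O`` = proportion of heterozygous calls
* Nei's standard genetic distance ``D`` (gene-identity form)
* pairwise ``F_ST`` in the G_ST ratio-of-sums form
* the Futschik–Schlötterer ``n/(n-1)`` correction for pool-seq ``H_E``

Frequencies may come from genotype matrices, individual sequences or pooled
sequencing; :class:`PopulationFrequencies` carries the values plus provenance.
Loci without data are encoded as NaN and dropped pairwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationFrequencies",
    "PairwiseDistanceResult",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "pool_correct_he",
    "nei_distance",
    "fst_pairwise",
    "pairwise_distance",
]


@dataclass
class PopulationFrequencies:
    """Per-locus alternate-allele frequencies for one population.

    Parameters
    ----------
    freq
        Length-L vector of alternate-allele frequencies in [0, 1];
        NaN marks loci without data.
    source
        Provenance tag: ``"genotypes"``, ``"individual-sequence"`` or
        ``"pooled-sequence"``.
    n_pool
        Number of haplotypes in the pool (pooled-sequence data only);
        the *n* of the ``n/(n-1)`` correction factor.
    label
        Population label, for bookkeeping.
    """

    freq: np.ndarray
    source: str = "genotypes"
    n_pool: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 1 or self.freq.size < 1:
            raise ValueError("freq must be a 1-D vector with at least one locus")
        finite = self.freq[np.isfinite(self.freq)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.freq.size

    @classmethod
    def from_genotypes(cls, genotypes, population: str | None = None,
                       individuals=None, label: str | None = None
                       ) -> "PopulationFrequencies":
        """Allele frequencies from non-missing 0/1/2 dosages.

        ``genotypes`` is any object with ``dosages`` (sites x individuals,
        -1 = missing) and ``populations`` (per-individual labels).
        """
        dos = np.asarray(genotypes.dosages)
        if individuals is None:
            if population is None:
                individuals = np.arange(dos.shape[1])
            else:
                individuals = np.flatnonzero(
                    np.asarray(genotypes.populations) == population)
        individuals = np.asarray(individuals)
        if individuals.size == 0:
            raise ValueError("empty individual subset")
        sub = dos[:, individuals].astype(float)
        sub[sub < 0] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(sub, axis=1) / 2.0
        return cls(freq, source="genotypes", label=label or population)

    @classmethod
    def from_pool(cls, pool) -> "PopulationFrequencies":
        """Wrap a pool-seq frequency estimate (``freq``, ``n_haplotypes``)."""
        return cls(np.asarray(pool.freq, dtype=float), source="pooled-sequence",
                   n_pool=int(pool.n_haplotypes), label=getattr(pool, "population", None))


@dataclass
class PairwiseDistanceResult:
    """Nei's D and F_ST for one population pair, with per-locus intermediates."""

    pop_x: str | None
    pop_y: str | None
    nei_d: float
    fst: float
    ht: np.ndarray = field(repr=False)
    hs_bar: np.ndarray = field(repr=False)


def _freq_vector(x) -> np.ndarray:
    if isinstance(x, PopulationFrequencies):
        return x.freq
    return np.asarray(x, dtype=float)


def expected_heterozygosity(freqs) -> float:
    """Mean over loci of ``2 p (1 - p)``; NaN loci are ignored."""
    p = _freq_vector(freqs)
    if p.size < 1:
        raise ValueError("empty locus set")
    het = 2.0 * p * (1.0 - p)
    if not np.isfinite(het).any():
        raise ValueError("no loci with defined frequency")
    return float(np.nanmean(het))


def observed_heterozygosity(genotypes, population: str | None = None,
                            individuals=None) -> float:
    """Proportion of heterozygous calls among all non-missing calls.

    Equivalent to the loci-then-individuals average when data are complete.
    """
    dos = np.asarray(genotypes.dosages)
    if individuals is None:
        if population is None:
            individuals = np.arange(dos.shape[1])
        else:
            individuals = np.flatnonzero(
                np.asarray(genotypes.populations) == population)
    sub = dos[:, np.asarray(individuals)]
    called = sub >= 0
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError("no non-missing genotype calls")
    return float((sub[called] == 1).sum() / n_called)


def pool_correct_he(h_e: float, n: int) -> float:
    """Futschik–Schlötterer correction: multiply pooled H_E by ``n/(n-1)``.

    ``n`` is the number of haplotypes in the pool. Removes the finite-pool
    component of the downward bias of pooled H_E (not the finite-coverage
    component, which vanishes only at high depth).
    """
    if n < 2:
        raise ValueError("pool must contain at least 2 haplotypes")
    return h_e * n / (n - 1.0)


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    px, py = _freq_vector(x), _freq_vector(y)
    if px.shape != py.shape:
        raise ValueError("populations must share the same locus set")
    keep = np.isfinite(px) & np.isfinite(py)
    return px[keep], py[keep]


def nei_distance(x, y) -> float:
    """Nei's standard genetic distance.

    ``D = -ln( sum_l sum_i x_il y_il / sqrt(sum_l sum_i x_il^2 * sum_l sum_i y_il^2) )``
    where the inner sums run over both alleles of each biallelic locus
    (p and 1-p). Returns ``+inf`` with a warning when the populations share
    no alleles at any locus.
    """
    px, py = _paired(x, y)
    if px.size == 0:
        raise ValueError("no loci with data in both populations")
    jxy = float(np.sum(px * py + (1 - px) * (1 - py)))
    jx = float(np.sum(px ** 2 + (1 - px) ** 2))
    jy = float(np.sum(py ** 2 + (1 - py) ** 2))
    if jxy == 0.0:
        warnings.warn("populations share no alleles; Nei's D is infinite",
                      RuntimeWarning, stacklevel=2)
        return float("inf")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def fst_pairwise(x, y) -> float:
    """Pairwise F_ST as a ratio of sums across loci (G_ST form).

    Per locus: total frequency = unweighted mean of the two population
    frequencies, ``HT = 2 pbar (1-pbar)``, ``HSbar`` = mean of the two
    within-population ``2 p (1-p)``; then
    ``F_ST = sum_l (HT_l - HSbar_l) / sum_l HT_l``.
    """
    px, py = _paired(x, y)
    if px.size == 0:
        raise ValueError("no loci with data in both populations")
    pbar = 0.5 * (px + py)
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = 0.5 * (2.0 * px * (1.0 - px) + 2.0 * py * (1.0 - py))
    ht_sum = float(ht.sum())
    if ht_sum == 0.0:
        raise ValueError("both populations identically monomorphic at every locus; "
                         "F_ST undefined")
    return float((ht_sum - float(hs.sum())) / ht_sum)


def pairwise_distance(x: PopulationFrequencies, y: PopulationFrequencies
                      ) -> PairwiseDistanceResult:
    """Nei's D and F_ST for one pair, keeping per-locus intermediates."""
    px, py = _paired(x, y)
    pbar = 0.5 * (px + py)
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = 0.5 * (2.0 * px * (1.0 - px) + 2.0 * py * (1.0 - py))
    return PairwiseDistanceResult(
        pop_x=getattr(x, "label", None), pop_y=getattr(y, "label", None),
        nei_d=nei_distance(x, y), fst=fst_pairwise(x, y), ht=ht, hs_bar=hs)
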