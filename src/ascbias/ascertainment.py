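"""In-silico SNP array design by discovery-population MAF filtering.

An array is "ascertained" by keeping only sites whose minor-allele frequency
within a chosen discovery population exceeds a threshold (strictly).  Sites
failing the filter are set to missing for every study individual rather than
deleted, so imputation can later address them.  An LD-pruning comparison arm
(sliding-window VIF pruning in the style of ``plink --indep``) is included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic_data import GenotypeMatrix

__all__ = [
    "AscertainmentMask",
    "compute_maf",
    "design_array",
    "apply_mask",
    "ld_prune",
]


@dataclass
class AscertainmentMask:
    """Sites retained by a discovery-population MAF filter."""

    sites: np.ndarray            # ordered retained site indices
    discovery_pop: str
    threshold: float

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.intp)
        if self.sites.size and np.any(np.diff(self.sites) <= 0):
            raise ValueError("mask sites must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return self.sites.size


def compute_maf(genotypes: GenotypeMatrix, individuals=None,
                population: str | None = None) -> np.ndarray:
    """Per-site minor-allele frequency from non-missing dosages.

    Returns NaN at sites with no non-missing call in the subset.
    """
    dos = genotypes.dosages
    if individuals is None:
        if population is not None:
            individuals = genotypes.individuals_of(population)
        else:
            individuals = np.arange(genotypes.n_individuals)
    individuals = np.asarray(individuals)
    if individuals.size == 0:
        raise ValueError("empty individual subset")
    sub = dos[:, individuals].astype(float)
    sub[sub < 0] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(sub, axis=1) / 2.0
    return np.minimum(p, 1.0 - p)


def design_array(genotypes: GenotypeMatrix, discovery_pop: str,
                 threshold: float = 0.05) -> AscertainmentMask:
    """Retain exactly the sites with discovery-population MAF > threshold.

    The inequality is strict: a site at exactly the threshold is excluded.
    Sites undefined in the discovery population (all calls missing) are
    excluded as undiscoverable.
    """
    if discovery_pop not in genotypes.populations:
        raise KeyError(f"unknown discovery population: {discovery_pop!r}")
    maf = compute_maf(genotypes, population=discovery_pop)
    with np.errstate(invalid="ignore"):
        keep = maf > threshold
    keep &= np.isfinite(maf)
    return AscertainmentMask(np.flatnonzero(keep), discovery_pop, threshold)


def apply_mask(genotypes: GenotypeMatrix, mask: AscertainmentMask
               ) -> GenotypeMatrix:
    """Set all sites outside the mask to missing for every individual.

    Site list and map are preserved (missingness encoding, not row deletion)
    so imputation targets remain addressable; retained sites are untouched.
    """
    if mask.sites.size and mask.sites[-1] >= genotypes.n_sites:
        raise ValueError("mask refers to sites outside the genotype matrix")
    out = genotypes.copy()
    drop = np.ones(genotypes.n_sites, dtype=bool)
    drop[mask.sites] = False
    out.dosages[drop, :] = -1
    return out


def _window_vifs(x: np.ndarray) -> np.ndarray:
    """VIF = 1/(1-R^2) for each column regressed on the remaining columns.

    ``x`` is an individuals x sites dosage block, already mean-imputed.
    Zero-variance columns get VIF 1 (nothing to explain or be explained by).
    """
    n, m = x.shape
    sd = x.std(axis=0)
    ok = sd > 0
    vif = np.ones(m)
    k = int(ok.sum())
    if k < 2:
        return vif
    z = (x[:, ok] - x[:, ok].mean(axis=0)) / sd[ok]
    r = (z.T @ z) / n
    # exact collinearity makes R singular: fall back to lstsq-based R^2
    try:
        rinv = np.linalg.inv(r)
        diag = np.diag(rinv)
        if np.all(diag > 0) and np.linalg.cond(r) < 1e10:
            vif[ok] = diag
            return vif
    except np.linalg.LinAlgError:
        pass
    vals = np.empty(k)
    for j in range(k):
        others = np.delete(np.arange(k), j)
        beta, *_ = np.linalg.lstsq(z[:, others], z[:, j], rcond=None)
        resid = z[:, j] - z[:, others] @ beta
        r2 = 1.0 - float(resid @ resid) / n
        vals[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    vif[ok] = vals
    return vif


def ld_prune(genotypes: GenotypeMatrix, window_snps: int = 50,
             step_snps: int = 5, vif_threshold: float = 2.0) -> np.ndarray:
    """Sliding-window VIF pruning of sites in LD (``--indep`` style).

    A window of ``window_snps`` sites advances by ``step_snps``; within each
    window the site with the highest VIF (ties: lowest index) is removed
    iteratively until all remaining VIFs are <= ``vif_threshold``.  Removal
    is global: a site removed in one window stays removed.  Returns the
    retained site indices, deterministic for a given input.
    """
    if not (window_snps > step_snps >= 1):
        raise ValueError("require window_snps > step_snps >= 1")
    if vif_threshold <= 1:
        raise ValueError("vif_threshold must exceed 1")
    dos = genotypes.dosages.T.astype(float)          # individuals x sites
    dos[dos < 0] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(dos), np.nan, dos), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    dos = np.where(np.isnan(dos), col_mean, dos)
    n_sites = genotypes.n_sites
    removed = np.zeros(n_sites, dtype=bool)
    start = 0
    while True:
        stop = min(start + window_snps, n_sites)
        idx = np.arange(start, stop)
        idx = idx[~removed[idx]]
        while idx.size >= 2:
            vif = _window_vifs(dos[:, idx])
            worst = int(np.argmax(vif))          # argmax takes lowest index on ties
            if vif[worst] <= vif_threshold:
                break
            removed[idx[worst]] = True
            idx = np.delete(idx, worst)
        if stop >= n_sites:
            break
        start += step_snps
    return np.flatnonzero(~removed)
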