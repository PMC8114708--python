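"""Bias quantification and imputation-quality assessment.

Populations are grouped by their role in a scenario (``discovery``,
``reference``, ``application``); biased estimates are regressed on the true
ones with group-specific intercepts and slopes (a perfectly unbiased data
set lies on the line of identity: slope 1, intercept 0), complemented by the
per-group mean relative overestimation and the within-group Pearson
correlation.  Imputation quality is the per-animal Pearson correlation
between true and imputed dosages at imputed sites, plus leave-one-out
validation of a reference panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ascertainment import AscertainmentMask
from .imputation import ImputerConfig, ImputationResult, impute_genotypes
from .reference_panels import ReferencePanel, filter_reference_sites
from .synthetic_data import GenotypeMatrix, HaplotypePanel

__all__ = [
    "GroupAssignment",
    "BiasReport",
    "assign_groups",
    "group_regression",
    "mean_overestimation",
    "per_animal_accuracy",
    "leave_one_out",
]

MIN_RELIABLE_POINTS = 3


@dataclass
class GroupAssignment:
    """Population -> role labels for one scenario cell."""

    labels: dict[str, str]
    discovery_pop: str

    def __getitem__(self, population: str) -> str:
        return self.labels[population]

    def pair(self, pop_a: str, pop_b: str) -> str:
        """Unordered group label for a population pair."""
        return "/".join(sorted((self.labels[pop_a], self.labels[pop_b])))


def assign_groups(populations, discovery_pop: str,
                  panel: ReferencePanel | None = None) -> GroupAssignment:
    """Label each population discovery / reference / application.

    Discovery takes precedence over reference, reference over application.
    When every population contributes reference individuals, the reference
    role is uninformative and non-discovery populations are all labelled
    application (two-group scheme).
    """
    populations = list(populations)
    if discovery_pop not in populations:
        raise KeyError(f"unknown discovery population: {discovery_pop!r}")
    ref_pops = set() if panel is None else set(panel.populations)
    all_covered = ref_pops.issuperset(populations)
    labels = {}
    for p in populations:
        if p == discovery_pop:
            labels[p] = "discovery"
        elif p in ref_pops and not all_covered:
            labels[p] = "reference"
        else:
            labels[p] = "application"
    return GroupAssignment(labels, discovery_pop)


@dataclass
class BiasReport:
    """Per-group regression of biased on true estimates.

    ``table`` columns: group, n, n_dropped, slope, intercept, sigma2, r,
    mean_overestimation, reliable.  Groups with fewer than 3 finite pairs or
    constant x are flagged unreliable (slope NaN where undefined) rather
    than silently reported.
    """

    table: pd.DataFrame

    def group(self, label: str) -> pd.Series:
        sub = self.table[self.table["group"] == label]
        if sub.empty:
            raise KeyError(f"no group {label!r} in report")
        return sub.iloc[0]


def mean_overestimation(biased, true) -> float:
    """Mean over populations of ``(biased_j - true_j) / true_j``.

    Populations with a true value of 0 (or a non-finite pair) are excluded
    with a warning, since the relative error is undefined there.
    """
    b = np.asarray(biased, dtype=float)
    t = np.asarray(true, dtype=float)
    if b.shape != t.shape:
        raise ValueError("biased and true must have the same length")
    ok = np.isfinite(b) & np.isfinite(t) & (t != 0.0)
    if ok.sum() < b.size:
        warnings.warn(f"excluding {b.size - int(ok.sum())} populations with "
                      "zero or non-finite true value", RuntimeWarning,
                      stacklevel=2)
    if not ok.any():
        raise ValueError("no populations with non-zero finite true value")
    return float(np.mean((b[ok] - t[ok]) / t[ok]))


def group_regression(true_values, biased_values, groups) -> BiasReport:
    """Per-group OLS of biased (y) on true (x) estimates.

    Fitting a separate intercept and slope per group is equivalent to the
    full-interaction model ``y_ij = group_i + group_i * beta_i * x_ij + e_ij``.
    Non-finite pairs are dropped per group with a recorded count.
    """
    x = np.asarray(true_values, dtype=float)
    y = np.asarray(biased_values, dtype=float)
    g = np.asarray(groups)
    if not (x.shape == y.shape == g.shape):
        raise ValueError("true, biased and groups must have the same length")
    rows = []
    for label in pd.unique(g):
        sel = g == label
        xs, ys = x[sel], y[sel]
        finite = np.isfinite(xs) & np.isfinite(ys)
        n_dropped = int(sel.sum() - finite.sum())
        xs, ys = xs[finite], ys[finite]
        n = xs.size
        slope = intercept = r = sigma2 = over = float("nan")
        reliable = n >= MIN_RELIABLE_POINTS
        if n >= 2 and np.ptp(xs) > 0:
            fit = stats.linregress(xs, ys)
            slope, intercept, r = float(fit.slope), float(fit.intercept), float(fit.rvalue)
            resid = ys - (intercept + slope * xs)
            sigma2 = float(resid @ resid / max(n - 2, 1))
        else:
            reliable = False
        if n >= 1 and np.any(xs != 0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                over = mean_overestimation(ys, xs)
        rows.append(dict(group=label, n=n, n_dropped=n_dropped, slope=slope,
                         intercept=intercept, sigma2=sigma2, r=r,
                         mean_overestimation=over, reliable=reliable))
    return BiasReport(pd.DataFrame(rows))


def per_animal_accuracy(true_genotypes: GenotypeMatrix,
                        result: ImputationResult) -> pd.DataFrame:
    """Pearson r between true and imputed dosages, per animal.

    Computed across imputed (masked) sites only; typed sites would inflate
    the correlation trivially.  Animals without at least two informative
    sites, or with zero variance in either vector, get r = NaN with the
    reason recorded.
    """
    rows = []
    for j, sample in enumerate(true_genotypes.samples):
        sel = (result.imputed_sites & ~result.typed[:, j]
               & (true_genotypes.dosages[:, j] >= 0)
               & np.isfinite(result.dosage[:, j]))
        t = true_genotypes.dosages[sel, j].astype(float)
        m = result.dosage[sel, j]
        r, reason = float("nan"), ""
        if t.size < 2:
            reason = "fewer than 2 imputed sites"
        elif np.ptp(t) == 0 or np.ptp(m) == 0:
            reason = "zero variance"
        else:
            r = float(stats.pearsonr(t, m).statistic)
        rows.append(dict(sample=sample,
                         population=true_genotypes.populations[j],
                         r=r, n_sites=int(t.size), reason=reason))
    return pd.DataFrame(rows)


def leave_one_out(truth: HaplotypePanel, mask: AscertainmentMask,
                  panel: ReferencePanel,
                  config: ImputerConfig | None = None,
                  maf_threshold: float = 0.01) -> pd.DataFrame:
    """Leave-one-out validation of a reference panel.

    Each panel individual in turn is removed from the panel, its non-array
    sites are masked, and it is imputed against the reduced panel (with the
    reference-site MAF filter recomputed).  The annotation records whether
    any same-population individual remained in the reduced panel — absence
    of one is the mechanism of downward-biased accuracy for populations
    with a single reference sample.
    """
    if panel.n_individuals < 2:
        raise ValueError("leave-one-out requires a panel of at least 2")
    config = config or ImputerConfig()
    genotypes = truth.to_genotypes()
    rows = []
    for pos in range(panel.n_individuals):
        test_idx = int(panel.individuals[pos])
        reduced_members = np.delete(panel.individuals, pos)
        reduced = replace(panel, individuals=reduced_members,
                          samples=np.delete(panel.samples, pos),
                          populations=np.delete(panel.populations, pos),
                          sites=None)
        reduced = filter_reference_sites(genotypes, reduced, maf_threshold)
        target = truth.subset_individuals(np.array([test_idx]))
        masked = target.copy()
        drop = np.ones(truth.n_sites, dtype=bool)
        drop[mask.sites] = False
        masked.alleles[drop, :] = -1
        ref_haps = truth.subset_individuals(reduced_members)
        res = impute_genotypes(masked, ref_haps, config,
                               reference_sites=reduced.sites)
        acc = per_animal_accuracy(
            genotypes.subset_individuals(np.array([test_idx])), res)
        pop = truth.populations[test_idx]
        rows.append(dict(sample=truth.samples[test_idx], population=pop,
                         r=float(acc["r"].iloc[0]),
                         n_sites=int(acc["n_sites"].iloc[0]),
                         same_pop_remaining=bool((reduced.populations == pop).any())))
    return pd.DataFrame(rows)
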