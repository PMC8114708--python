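"""Scenario orchestration and file I/O.

A scenario sweep runs, for every (discovery population x strategy x panel
size x repetition) cell: in-silico array design by discovery-population MAF
filtering, reference-panel sampling, reference-site filtering,
haplotype-copying imputation, and estimator evaluation on the true,
ascertained and imputed data.  Truth data is simulated once per scenario and
shared across cells; each cell's randomness derives from a child seed that
is a stable hash of (master seed, cell identifiers), so any cell can be
reproduced in isolation.

File formats: VCF for genotypes/haplotypes (GT, plus DS and site-level DR2
INFO on imputed output), PLINK-style 4-column genetic maps
(chrom, id, cM, bp), 2-column TSV population files, one-column site-ID
lists, YAML scenario configs and tidy TSV result tables.  VCF coordinates
are 1-based; internal site indices are 0-based.
"""

from __future__ import annotations

import hashlib
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import estimators
from .ascertainment import apply_mask, design_array
from .evaluation import assign_groups, group_regression, per_animal_accuracy, BiasReport
from .imputation import ImputerConfig, impute_genotypes
from .reference_panels import (STRATEGIES, filter_reference_sites,
                               population_distance_matrix, sample_reference)
from .synthetic_data import (GeneticMap, GenotypeMatrix, HaplotypePanel,
                             PopulationModel, simulate_dataset)

logger = logging.getLogger("ascbias")

__all__ = [
    "ScenarioConfig", "RunRecord", "ScenarioResult", "ConfigError",
    "FormatError", "run_scenario", "pooled_regression", "child_seed",
    "default_study_config", "study_metrics",
    "read_config", "write_vcf", "read_vcf", "write_map", "read_map",
    "write_popfile", "read_popfile", "write_sites", "read_sites",
]


class ConfigError(ValueError):
    """Invalid scenario configuration."""


class FormatError(ValueError):
    """Invalid input file contents."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Everything needed to reproduce one scenario sweep.

    ``strategies`` maps a strategy name to a list of sizes, where size means
    individuals per population for ``allPop``, total individuals for
    ``randSamp`` and number of populations for ``randPop``/``minPop``/
    ``maxPop`` (x 5 individuals each).
    """

    model: PopulationModel = field(default_factory=PopulationModel)
    n_individuals_per_pop: int = 20
    span_cm: float = 100.0
    discovery_pops: list[str] | None = None
    maf_discovery: float = 0.05
    maf_reference: float = 0.01
    strategies: dict[str, list[int]] = field(
        default_factory=lambda: {"allPop": [1]})
    repetitions: int = 1
    master_seed: int = 0
    imputer: ImputerConfig = field(default_factory=ImputerConfig)
    compute_pairs: bool = True
    resimulate_per_cell: bool = False

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        if not self.strategies:
            raise ConfigError("strategies must be non-empty")
        for s, sizes in self.strategies.items():
            if s not in STRATEGIES:
                raise ConfigError(f"unknown strategy {s!r}; expected one of "
                                  f"{STRATEGIES}")
            if not sizes:
                raise ConfigError(f"empty size grid for strategy {s!r}")


def read_config(path) -> ScenarioConfig:
    """Load and validate a YAML scenario configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    for key in ("model", "strategies"):
        if key not in raw:
            raise ConfigError(f"{path}: missing required key: {key!r}")
    try:
        model = PopulationModel(**raw.pop("model"))
    except TypeError as exc:
        raise ConfigError(f"{path}: invalid model section: {exc}") from None
    imputer = ImputerConfig(**raw.pop("imputer", {}))
    try:
        return ScenarioConfig(model=model, imputer=imputer, **raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def child_seed(master_seed: int, *cell) -> int:
    """Stable child seed (< 2^31) from the master seed and cell identifiers."""
    key = ":".join([str(master_seed), *map(str, cell)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# scenario sweep
# ---------------------------------------------------------------------------

@dataclass
class RunRecord:
    """Identifiers, status and artifacts of one scenario cell."""

    discovery_pop: str
    strategy: str
    size: int
    repetition: int
    seed: int
    status: str = "ok"
    error: str = ""
    n_array_sites: int = 0
    n_reference_sites: int = 0
    duration_s: float = 0.0


@dataclass
class ScenarioResult:
    """Tidy result tables of one scenario sweep, joinable on cell ids."""

    per_population: pd.DataFrame
    pairs: pd.DataFrame
    accuracy: pd.DataFrame
    records: list[RunRecord]

    @property
    def n_failed(self) -> int:
        return sum(r.status != "ok" for r in self.records)


def _strategy_params(strategy: str, size: int) -> dict:
    if strategy == "allPop":
        return {"k": size}
    if strategy == "randSamp":
        return {"m": size}
    return {"q": size, "per_pop": 5}


def _pop_stats(genotypes: GenotypeMatrix, pops: Iterable[str]) -> dict:
    out = {}
    for p in pops:
        try:
            f = estimators.PopulationFrequencies.from_genotypes(genotypes, p)
            out[p] = (estimators.expected_heterozygosity(f),
                      estimators.observed_heterozygosity(genotypes, p), f)
        except ValueError:
            out[p] = (float("nan"), float("nan"), None)
    return out


def _pair_stats(stats: dict, pops: list[str]) -> dict:
    out = {}
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            fa, fb = stats[a][2], stats[b][2]
            if fa is None or fb is None:
                out[(a, b)] = (float("nan"), float("nan"))
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                try:
                    out[(a, b)] = (estimators.nei_distance(fa, fb),
                                   estimators.fst_pairwise(fa, fb))
                except ValueError:
                    out[(a, b)] = (float("nan"), float("nan"))
    return out


def run_scenario(config: ScenarioConfig, outdir=None) -> ScenarioResult:
    """Run a full scenario sweep; fail-soft per cell.

    Returns tidy per-population, pairwise and per-animal accuracy tables
    keyed by (discovery_pop, strategy, size, repetition).  With ``outdir``,
    the tables and per-cell records are also written as TSV.
    """
    truth = simulate_dataset(config.model, config.n_individuals_per_pop,
                             span_cm=config.span_cm)
    pops = truth.genotypes.population_labels
    discovery_pops = config.discovery_pops or pops
    needs_dist = any(s in ("minPop", "maxPop") for s in config.strategies)
    distances = population_distance_matrix(truth.genotypes) if needs_dist else None

    true_stats = _pop_stats(truth.genotypes, pops)
    true_pairs = _pair_stats(true_stats, pops) if config.compute_pairs else {}

    pop_rows, pair_rows, acc_rows, records = [], [], [], []
    for disc in discovery_pops:
        mask = design_array(truth.genotypes, disc, config.maf_discovery)
        masked = apply_mask(truth.genotypes, mask)
        asc_stats = _pop_stats(masked, pops)
        asc_pairs = _pair_stats(asc_stats, pops) if config.compute_pairs else {}
        masked_haps = truth.haplotypes.copy()
        drop = np.ones(truth.gmap.n_sites, dtype=bool)
        drop[mask.sites] = False
        masked_haps.alleles[drop, :] = -1

        for strategy, sizes in config.strategies.items():
            for size in sizes:
                for rep in range(config.repetitions):
                    seed = child_seed(config.master_seed, disc, strategy,
                                      size, rep)
                    rec = RunRecord(disc, strategy, size, rep, seed)
                    t0 = time.perf_counter()
                    try:
                        panel = sample_reference(
                            strategy, _strategy_params(strategy, size),
                            truth.genotypes, discovery_pop=disc,
                            distances=distances, seed=seed)
                        panel = filter_reference_sites(
                            truth.genotypes, panel, config.maf_reference)
                        ref_haps = truth.haplotypes.subset_individuals(
                            panel.individuals)
                        res = impute_genotypes(masked_haps, ref_haps,
                                               config.imputer,
                                               reference_sites=panel.sites)
                        imputed = GenotypeMatrix(
                            res.best_guess, truth.genotypes.samples,
                            truth.genotypes.populations, truth.gmap)
                        imp_stats = _pop_stats(imputed, pops)
                        imp_pairs = (_pair_stats(imp_stats, pops)
                                     if config.compute_pairs else {})
                        groups = assign_groups(pops, disc, panel)
                        cell = dict(discovery_pop=disc, strategy=strategy,
                                    size=size, repetition=rep, seed=seed)
                        for p in pops:
                            pop_rows.append(dict(
                                cell, population=p, group=groups[p],
                                he_true=true_stats[p][0],
                                ho_true=true_stats[p][1],
                                he_ascertained=asc_stats[p][0],
                                ho_ascertained=asc_stats[p][1],
                                he_imputed=imp_stats[p][0],
                                ho_imputed=imp_stats[p][1]))
                        for (a, b), (d_t, f_t) in true_pairs.items():
                            d_a, f_a = asc_pairs[(a, b)]
                            d_i, f_i = imp_pairs[(a, b)]
                            pair_rows.append(dict(
                                cell, pop_a=a, pop_b=b, group=groups.pair(a, b),
                                d_true=d_t, fst_true=f_t,
                                d_ascertained=d_a, fst_ascertained=f_a,
                                d_imputed=d_i, fst_imputed=f_i))
                        acc = per_animal_accuracy(truth.genotypes, res)
                        acc["group"] = [groups[p] for p in acc["population"]]
                        for k, v in reversed(cell.items()):
                            acc.insert(0, k, v)
                        acc_rows.append(acc)
                        rec.n_array_sites = mask.n_sites
                        rec.n_reference_sites = (0 if panel.sites is None
                                                 else panel.sites.size)
                    except Exception as exc:  # fail-soft per cell
                        rec.status, rec.error = "failed", str(exc)
                        logger.warning("cell %s/%s/%s/%s failed: %s", disc,
                                       strategy, size, rep, exc)
                    rec.duration_s = round(time.perf_counter() - t0, 3)
                    logger.info("cell discovery=%s strategy=%s size=%s rep=%s "
                                "status=%s duration=%.2fs", disc, strategy,
                                size, rep, rec.status, rec.duration_s)
                    records.append(rec)

    result = ScenarioResult(
        pd.DataFrame(pop_rows),
        pd.DataFrame(pair_rows),
        (pd.concat(acc_rows, ignore_index=True) if acc_rows else pd.DataFrame()),
        records)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.per_population.to_csv(outdir / "per_population.tsv", sep="\t",
                                     index=False)
        result.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        result.accuracy.to_csv(outdir / "accuracy.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(r) for r in records]).to_csv(
            outdir / "records.tsv", sep="\t", index=False)
    return result


def default_study_config(seed: int,
                         strategies: dict[str, list[int]] | None = None
                         ) -> ScenarioConfig:
    """Canonical bias-study conditions for one replicate.

    10 populations of 20 individuals at 5,000 sites on a 100 cM map, with
    per-population drift evenly spaced on [0.05, 0.25] (mean 0.15) so the
    panel spans low- to high-diversity populations, as a mixed panel of
    commercial lines and wild populations would.  Arrays are ascertained at
    MAF > 0.05 in each discovery population in turn; reference panels default
    to a balanced one-per-population panel and an unbalanced two-most-distant-
    populations panel of equal total size.
    """
    drift = np.linspace(0.05, 0.25, 10)
    return ScenarioConfig(
        model=PopulationModel(n_populations=10, drift_F=drift, n_sites=5000,
                              seed=seed),
        n_individuals_per_pop=20, span_cm=100.0,
        strategies=strategies or {"allPop": [1], "maxPop": [2]},
        repetitions=1, master_seed=seed)


def study_metrics(result: ScenarioResult) -> dict[str, float]:
    """Per-replicate bias indicators from one scenario sweep.

    Group-specific slopes, correlations and mean overestimation of the
    ascertained and imputed heterozygosity estimates (pooled over discovery
    populations), the same for the unbalanced panel, median per-animal
    imputation accuracy by group, and mixed-pair slopes for Nei's D and F_ST.
    """
    pp = result.per_population
    out: dict[str, float] = {}
    balanced = pp[pp["strategy"] == "allPop"]
    for col, tag in [("he_ascertained", "asc"), ("he_imputed", "imp")]:
        rep = pooled_regression(balanced, col)
        for _, row in rep.table.iterrows():
            g = "disc" if row["group"] == "discovery" else "app"
            out[f"he_slope_{tag}_{g}"] = row["slope"]
            out[f"he_corr_{tag}_{g}"] = row["r"]
            out[f"he_over_{tag}_{g}"] = row["mean_overestimation"]
    for col, tag in [("ho_ascertained", "asc"), ("ho_imputed", "imp")]:
        rep = pooled_regression(balanced, col, true_col="ho_true")
        for _, row in rep.table.iterrows():
            g = "disc" if row["group"] == "discovery" else "app"
            out[f"ho_slope_{tag}_{g}"] = row["slope"]
            out[f"ho_over_{tag}_{g}"] = row["mean_overestimation"]
    unbalanced = pp[pp["strategy"] == "maxPop"]
    if len(unbalanced):
        rep = pooled_regression(unbalanced, "he_imputed")
        app = rep.table[rep.table["group"] == "application"].iloc[0]
        out["he_slope_imp_app_maxpop"] = app["slope"]
        out["he_corr_imp_app_maxpop"] = app["r"]
        out["he_over_imp_app_maxpop"] = app["mean_overestimation"]
    acc = result.accuracy
    acc = acc[acc["strategy"] == "allPop"]
    med = acc.groupby("group")["r"].median()
    out["accuracy_disc"] = float(med.get("discovery", float("nan")))
    out["accuracy_app"] = float(med.get("application", float("nan")))
    pairs = result.pairs
    mixed = pairs[(pairs["strategy"] == "allPop")
                  & (pairs["group"] == "application/discovery")]
    for stat in ("d", "fst"):
        rep = group_regression(mixed[f"{stat}_true"].to_numpy(),
                               mixed[f"{stat}_ascertained"].to_numpy(),
                               np.repeat("mixed", len(mixed)))
        out[f"{stat}_slope_asc_mixed"] = float(rep.table["slope"].iloc[0])
    return out


def pooled_regression(per_population: pd.DataFrame, biased_col: str,
                      true_col: str = "he_true",
                      group_col: str = "group") -> BiasReport:
    """Group regression pooling all cells of a scenario table."""
    return group_regression(per_population[true_col].to_numpy(),
                            per_population[biased_col].to_numpy(),
                            per_population[group_col].to_numpy())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DR2,Number=1,Type=Float,Description='
    '"Estimated squared correlation between imputed and true allele dose">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DS,Number=1,Type=Float,Description='
    '"Estimated alternate allele dosage">',
]


def write_vcf(path, data, dosage: np.ndarray | None = None,
              dr2: np.ndarray | None = None) -> None:
    """Write a GenotypeMatrix (unphased GT) or HaplotypePanel (phased GT).

    ``dosage`` adds a DS FORMAT field and ``dr2`` a site-level DR2 INFO
    field, mirroring the conventions of imputation tools.
    """
    phased = isinstance(data, HaplotypePanel)
    gmap = data.gmap
    with open(path, "w") as fh:
        for line in _VCF_HEADER:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, data.samples)) + "\n")
        fmt = "GT:DS" if dosage is not None else "GT"
        for s in range(data.n_sites):
            info = (f"DR2={dr2[s]:.4f}" if dr2 is not None
                    and np.isfinite(dr2[s]) else ".")
            if phased:
                hap = data.alleles[s]
                gts = [f"{_a(hap[2 * j])}|{_a(hap[2 * j + 1])}"
                       for j in range(data.n_individuals)]
            else:
                gts = [_GT_CODES[d] for d in data.dosages[s]]
            if dosage is not None:
                gts = [f"{g}:{dosage[s, j]:.3f}"
                       if np.isfinite(dosage[s, j]) else f"{g}:."
                       for j, g in enumerate(gts)]
            fh.write(f"{gmap.chrom[s]}\t{gmap.bp[s]}\t{gmap.ids[s]}\tA\tC\t.\t"
                     f"PASS\t{info}\t{fmt}\t" + "\t".join(gts) + "\n")


def _a(allele: int) -> str:
    return "." if allele < 0 else str(int(allele))


_GT_CODES = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def read_vcf(path, phased: bool = False, populations=None,
             gmap: GeneticMap | None = None, strict: bool = True,
             cm_per_mb: float = 1.0):
    """Read a biallelic-SNP VCF into a GenotypeMatrix or HaplotypePanel.

    Multi-allelic or non-SNP records raise a :class:`FormatError` naming
    the record in strict mode, otherwise they are skipped with a logged
    count.  Without an explicit genetic map, cM positions are derived from
    bp at ``cm_per_mb``.  ``populations`` maps sample -> population
    (default: a single population "pop1").
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    chroms, bps, ids, rows = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            if strict:
                raise FormatError(
                    f"{path}: record {var.CHROM}:{var.POS} "
                    f"({var.REF}>{','.join(var.ALT)}) is not a biallelic SNP")
            n_skipped += 1
            continue
        chroms.append(var.CHROM)
        bps.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        if phased:
            row = np.empty(2 * samples.size, dtype=np.int8)
            for j, g in enumerate(var.genotypes):
                row[2 * j] = -1 if g[0] < 0 else g[0]
                row[2 * j + 1] = -1 if g[1] < 0 else g[1]
        else:
            row = np.empty(samples.size, dtype=np.int8)
            for j, g in enumerate(var.genotypes):
                row[j] = -1 if (g[0] < 0 or g[1] < 0) else g[0] + g[1]
        rows.append(row)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise FormatError(f"{path}: no biallelic SNP records")
    mat = np.vstack(rows)
    if gmap is None:
        gmap = GeneticMap(np.asarray(chroms, dtype=object),
                          np.asarray(bps, dtype=np.int64),
                          np.asarray(bps, dtype=float) * cm_per_mb * 1e-6,
                          np.asarray(ids, dtype=object))
    elif gmap.n_sites != mat.shape[0]:
        raise FormatError(f"{path}: genetic map covers {gmap.n_sites} sites "
                          f"but the VCF has {mat.shape[0]}")
    if populations is None:
        pops = np.repeat("pop1", samples.size).astype(object)
    else:
        pops = np.asarray([populations[s] for s in samples], dtype=object)
    if phased:
        return HaplotypePanel(mat, samples, pops, gmap)
    return GenotypeMatrix(mat, samples, pops, gmap)


# ---------------------------------------------------------------------------
# small text formats
# ---------------------------------------------------------------------------

def write_map(path, gmap: GeneticMap) -> None:
    """PLINK-style 4-column map: chrom, id, cM, bp."""
    with open(path, "w") as fh:
        for s in range(gmap.n_sites):
            fh.write(f"{gmap.chrom[s]}\t{gmap.ids[s]}\t{gmap.cm[s]:.8g}\t"
                     f"{gmap.bp[s]}\n")


def read_map(path) -> GeneticMap:
    """Read a PLINK-style map, reporting offending line numbers."""
    chroms, ids, cms, bps = [], [], [], []
    last: dict[str, tuple[float, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns "
                                  f"(chrom, id, cM, bp), got {len(parts)}")
            chrom, sid, cm_s, bp_s = parts
            try:
                cm, bp = float(cm_s), int(bp_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed cM/bp") from None
            if chrom in last:
                prev_cm, prev_bp = last[chrom]
                if cm < prev_cm:
                    raise FormatError(f"{path}:{lineno}: cM decreasing "
                                      f"within chromosome {chrom}")
                if bp <= prev_bp:
                    raise FormatError(f"{path}:{lineno}: bp not strictly "
                                      f"increasing within chromosome {chrom}")
            last[chrom] = (cm, bp)
            chroms.append(chrom); ids.append(sid); cms.append(cm); bps.append(bp)
    if not chroms:
        raise FormatError(f"{path}: empty map file")
    return GeneticMap(np.asarray(chroms, dtype=object),
                      np.asarray(bps, dtype=np.int64), np.asarray(cms),
                      np.asarray(ids, dtype=object))


def write_popfile(path, samples, populations) -> None:
    pd.DataFrame({"individual": samples, "population": populations}).to_csv(
        path, sep="\t", index=False, header=False)


def read_popfile(path) -> dict[str, str]:
    """2-column TSV (individual, population) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns, got {df.shape[1]}")
    return dict(zip(df[0], df[1]))


def write_sites(path, ids: Iterable) -> None:
    """One-column site-ID list (plink extract-list style)."""
    with open(path, "w") as fh:
        for sid in ids:
            fh.write(f"{sid}\n")


def read_sites(path) -> np.ndarray:
    with open(path) as fh:
        return np.asarray([ln.strip() for ln in fh if ln.strip()], dtype=object)
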