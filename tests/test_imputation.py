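"""Tests of the haplotype-copying HMM imputer against exhaustive oracles."""

import itertools

import numpy as np
import pytest

from ascbias import (GeneticMap, HaplotypePanel, ImputerConfig, compute_dr2,
                     impute_genotypes, impute_haplotype, ls_state_posteriors,
                     recombination_weights)
from ascbias.imputation import _window_plan


def enumerate_allele_posteriors(obs, ref, rho, eps):
    """Independent oracle: sum over all K^S copy paths of the mosaic model."""
    S, K = ref.shape
    emis = np.where(obs[:, None] < 0, 1.0,
                    np.where(ref == obs[:, None], 1.0 - eps, eps))
    post = np.zeros(S)
    z = 0.0
    for path in itertools.product(range(K), repeat=S):
        w = emis[0, path[0]] / K
        for s in range(1, S):
            stay = 1.0 - rho[s - 1] + rho[s - 1] / K
            w *= (stay if path[s] == path[s - 1] else rho[s - 1] / K)
            w *= emis[s, path[s]]
        z += w
        for s in range(S):
            post[s] += w * ref[s, path[s]]
    return post / z


def map_for_rho(rho, ne=1000.0, k=2):
    """Genetic map whose adjacent distances reproduce the given switch probs."""
    d = -np.log(1.0 - np.asarray(rho)) * k / (0.04 * ne)
    cm = np.concatenate([[0.0], np.cumsum(d)])
    bp = np.arange(1, cm.size + 1) * 100
    return GeneticMap(np.repeat("1", cm.size), bp, cm)


class TestRecombinationWeights:
    def test_zero_distance_zero_switch(self):
        gmap = GeneticMap(np.repeat("1", 3), [1, 2, 3], [0.0, 0.0, 1.0])
        rho = recombination_weights(gmap, ne=1000, n_ref_haplotypes=20)
        assert rho[0] == 0.0

    def test_formula_value(self):
        gmap = GeneticMap(np.repeat("1", 2), [1, 2], [0.0, 0.01])
        rho = recombination_weights(gmap, ne=1000, n_ref_haplotypes=20)
        assert rho[0] == pytest.approx(1 - np.exp(-0.02), abs=1e-12)

    def test_saturates_below_one(self):
        gmap = GeneticMap(np.repeat("1", 2), [1, 2], [0.0, 50.0])
        rho = recombination_weights(gmap, ne=1e9, n_ref_haplotypes=2)
        assert rho[0] <= 1.0
        assert rho[0] == pytest.approx(1.0)

    def test_chromosome_boundary_free_recombination(self):
        gmap = GeneticMap(np.array(["1", "1", "2"], dtype=object),
                          [1, 2, 1], [0.0, 0.0, 0.0])
        rho = recombination_weights(gmap, ne=1000, n_ref_haplotypes=4)
        assert rho[1] == 1.0

    def test_zero_reference_haplotypes_rejected(self):
        gmap = GeneticMap.uniform(3)
        with pytest.raises(ValueError):
            recombination_weights(gmap, 1000, 0)


class TestImputeHaplotype:
    def test_perfect_match_copies_matching_reference(self):
        rng = np.random.default_rng(0)
        S = 30
        ref = rng.integers(0, 2, size=(S, 4)).astype(np.int8)
        ref[:, 0] = (np.arange(S) % 2)       # distinctive pattern
        ref[:, 1:] = 1 - ref[:, :1]          # all others disagree everywhere
        obs = ref[:, 0].copy()
        masked = slice(10, 20)
        obs[masked] = -1
        # short map: the copying state persists across the masked stretch
        gmap = GeneticMap.uniform(S, span_cm=0.002)
        post = impute_haplotype(obs, ref, gmap, ImputerConfig(error_rate=1e-6))
        target = ref[masked, 0].astype(float)
        np.testing.assert_allclose(post[masked], target, atol=0.01)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            S = int(rng.integers(2, 5))
            K = int(rng.integers(1, 4))
            ref = rng.integers(0, 2, size=(S, K)).astype(np.int8)
            obs = rng.integers(-1, 2, size=S).astype(np.int8)
            rho = rng.uniform(0.01, 0.9, size=S - 1)
            eps = float(rng.uniform(0.01, 0.4))
            gmap = map_for_rho(rho, k=K)
            got = impute_haplotype(obs, ref, gmap, ImputerConfig(error_rate=eps))
            want = enumerate_allele_posteriors(obs, ref,
                                               recombination_weights(gmap, 1000, K),
                                               eps)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_no_typed_sites_falls_back_to_reference_frequencies(self):
        rng = np.random.default_rng(2)
        ref = rng.integers(0, 2, size=(12, 6)).astype(np.int8)
        obs = np.full(12, -1, dtype=np.int8)
        gmap = GeneticMap.uniform(12, span_cm=3.0)
        post = impute_haplotype(obs, ref, gmap)
        np.testing.assert_allclose(post, ref.mean(axis=1), atol=1e-12)

    def test_zero_length_map_constant_state(self):
        # all sites at the same cM: no recombination, so a single typed site
        # pins the copied template everywhere
        ref = np.array([[0, 1], [0, 1], [0, 1], [0, 1]], dtype=np.int8)
        obs = np.array([1, -1, -1, -1], dtype=np.int8)
        gmap = GeneticMap(np.repeat("1", 4), [1, 2, 3, 4], [0.0] * 4)
        post = impute_haplotype(obs, ref, gmap, ImputerConfig(error_rate=1e-6))
        np.testing.assert_allclose(post, 1.0, atol=1e-5)

    def test_state_posteriors_normalized(self):
        rng = np.random.default_rng(3)
        ref = rng.integers(0, 2, size=(20, 5)).astype(np.int8)
        obs = rng.integers(-1, 2, size=20).astype(np.int8)
        gamma = ls_state_posteriors(obs, ref, np.full(19, 0.2), 0.05)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
        assert (gamma >= 0).all()


class TestDr2:
    def test_certain_polymorphic_posteriors(self):
        assert compute_dr2(np.array([0.0, 1.0, 1.0, 0.0])) == 1.0

    def test_no_information_is_zero(self):
        assert compute_dr2(np.array([0.3, 0.3, 0.3])) == 0.0

    def test_hand_example(self):
        # between-haplotype variance 0.16, mean within variance 0.09
        assert compute_dr2(np.array([0.9, 0.1])) == pytest.approx(0.64)

    def test_degenerate_all_fixed(self):
        assert np.isnan(compute_dr2(np.array([0.0, 0.0])))

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            compute_dr2(np.array([0.5]))


def _panel(alleles, pops, gmap=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    n_ind = alleles.shape[1] // 2
    if gmap is None:
        gmap = GeneticMap.uniform(alleles.shape[0], span_cm=10.0)
    return HaplotypePanel(alleles, np.array([f"s{i}" for i in range(n_ind)],
                                            dtype=object),
                          np.asarray(pops, dtype=object), gmap)


class TestImputeGenotypes:
    def test_no_masked_sites_identity(self, small_dataset):
        study = small_dataset.haplotypes
        res = impute_genotypes(study, study)
        np.testing.assert_array_equal(res.best_guess,
                                      small_dataset.genotypes.dosages)
        assert res.typed.all()
        # defined DR2 only where both values occur
        defined = np.isfinite(res.dr2)
        assert (res.dr2[defined] == 1.0).all()

    def test_self_reference_recovers_truth(self, small_dataset):
        truth = small_dataset.haplotypes
        masked = truth.copy()
        hidden = np.arange(0, truth.n_sites, 3)
        masked.alleles[hidden, :] = -1
        res = impute_genotypes(masked, truth, ImputerConfig(error_rate=1e-6))
        exact = (res.best_guess[hidden]
                 == small_dataset.genotypes.dosages[hidden]).mean()
        assert exact > 0.99

    def test_conservation_of_typed_genotypes(self, small_dataset):
        truth = small_dataset.haplotypes
        masked = truth.copy()
        hidden = np.arange(1, truth.n_sites, 2)
        masked.alleles[hidden, :] = -1
        ref = truth.subset_individuals(np.arange(0, truth.n_individuals, 4))
        res = impute_genotypes(masked, ref)
        typed_sites = np.setdiff1d(np.arange(truth.n_sites), hidden)
        np.testing.assert_array_equal(
            res.best_guess[typed_sites],
            small_dataset.genotypes.dosages[typed_sites])
        np.testing.assert_array_equal(
            res.dosage[typed_sites],
            small_dataset.genotypes.dosages[typed_sites].astype(float))

    def test_dosage_is_sum_of_haplotype_posteriors(self, small_dataset):
        truth = small_dataset.haplotypes
        masked = truth.copy()
        masked.alleles[::2, :] = -1
        ref = truth.subset_individuals(np.arange(0, truth.n_individuals, 3))
        res = impute_genotypes(masked, ref)
        expect = res.posteriors[:, 0::2] + res.posteriors[:, 1::2]
        np.testing.assert_allclose(res.dosage, expect, atol=1e-12)
        ok = np.isfinite(res.dr2)
        assert ((res.dr2[ok] >= 0) & (res.dr2[ok] <= 1)).all()

    def test_sites_outside_reference_set_stay_missing(self):
        truth = _panel(np.array([[0, 1], [1, 1], [0, 0]]), ["P1"])
        masked = truth.copy()
        masked.alleles[:] = -1
        masked.alleles[1] = truth.alleles[1]
        res = impute_genotypes(masked, truth,
                               reference_sites=np.array([1, 2]))
        assert res.best_guess[0, 0] == -1           # not typed, not reference
        assert np.isnan(res.dosage[0, 0])
        assert not res.imputed_sites[0]
        assert res.imputed_sites[2]

    def test_window_stitching_covers_all_sites_once(self):
        gpos = np.linspace(0, 100, 501)
        plan = _window_plan(gpos, window_cm=20.0, overlap_frac=0.1)
        seen = np.concatenate([lo + take for lo, hi, take in plan])
        np.testing.assert_array_equal(np.sort(seen), np.arange(501))

    def test_windowed_equals_unwindowed_when_ld_local(self, small_dataset):
        truth = small_dataset.haplotypes
        masked = truth.copy()
        masked.alleles[::4, :] = -1
        ref = truth.subset_individuals(np.arange(0, truth.n_individuals, 4))
        wide = impute_genotypes(masked, ref, ImputerConfig(window_cm=500.0))
        narrow = impute_genotypes(masked, ref, ImputerConfig(window_cm=20.0))
        # stitched posteriors agree closely away from hard window effects
        diff = np.nanmedian(np.abs(wide.posteriors - narrow.posteriors))
        assert diff < 0.02
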