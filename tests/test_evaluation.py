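"""Tests of group assignment, bias regression and accuracy assessment."""

import numpy as np
import pytest

from ascbias import (GenotypeMatrix, ImputerConfig, PopulationModel,
                     assign_groups, design_array, group_regression,
                     leave_one_out, mean_overestimation, per_animal_accuracy,
                     sample_reference, simulate_dataset)
from ascbias.imputation import ImputationResult


class FakePanel:
    def __init__(self, populations):
        self.populations = np.asarray(populations, dtype=object)


class TestAssignGroups:
    POPS = ["P1", "P2", "P3", "P4"]

    def test_reference_everywhere_collapses_to_two_groups(self):
        groups = assign_groups(self.POPS, "P3", FakePanel(self.POPS))
        assert groups["P3"] == "discovery"
        assert all(groups[p] == "application" for p in self.POPS if p != "P3")

    def test_three_group_scheme(self):
        groups = assign_groups(self.POPS, "P3", FakePanel(["P1", "P2"]))
        assert groups["P3"] == "discovery"
        assert groups["P1"] == groups["P2"] == "reference"
        assert groups["P4"] == "application"

    def test_discovery_precedence_over_reference(self):
        groups = assign_groups(self.POPS, "P1", FakePanel(["P1", "P2"]))
        assert groups["P1"] == "discovery"

    def test_pair_labels_unordered(self):
        groups = assign_groups(self.POPS, "P1", FakePanel(["P2"]))
        assert groups.pair("P1", "P4") == groups.pair("P4", "P1")
        assert groups.pair("P1", "P4") == "application/discovery"

    def test_unknown_discovery_rejected(self):
        with pytest.raises(KeyError):
            assign_groups(self.POPS, "P9", None)


class TestGroupRegression:
    def test_identity_line(self):
        x = np.array([0.1, 0.2, 0.3, 0.15, 0.25, 0.35])
        g = np.array(["a"] * 3 + ["b"] * 3)
        rep = group_regression(x, x, g)
        for label in ("a", "b"):
            row = rep.group(label)
            assert row.slope == pytest.approx(1.0, abs=1e-12)
            assert row.intercept == pytest.approx(0.0, abs=1e-12)
            assert row.r == pytest.approx(1.0, abs=1e-12)

    def test_four_point_closed_form(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        y = np.array([0.25, 0.40, 0.55, 0.70])
        rep = group_regression(x, y, np.repeat("g", 4))
        row = rep.group("g")
        assert row.slope == pytest.approx(1.5, abs=1e-9)
        assert row.intercept == pytest.approx(0.10, abs=1e-9)

    def test_groups_fitted_independently(self):
        x = np.array([0.1, 0.2, 0.3] * 2)
        y = np.array([0.2, 0.4, 0.6] * 2)
        g = np.array(["a"] * 3 + ["b"] * 3)
        rep = group_regression(x, y, g)
        assert rep.group("a").slope == rep.group("b").slope

    def test_nonfinite_pairs_dropped_with_count(self):
        x = np.array([0.1, 0.2, 0.3, np.inf])
        y = np.array([0.1, 0.2, 0.3, 0.4])
        rep = group_regression(x, y, np.repeat("g", 4))
        assert rep.group("g").n == 3
        assert rep.group("g").n_dropped == 1

    def test_constant_x_flagged(self):
        x = np.repeat(0.3, 4)
        y = np.array([0.1, 0.2, 0.3, 0.4])
        rep = group_regression(x, y, np.repeat("g", 4))
        assert not rep.group("g").reliable
        assert np.isnan(rep.group("g").slope)

    def test_small_group_flagged_unreliable(self):
        rep = group_regression(np.array([0.1, 0.4]), np.array([0.2, 0.5]),
                               np.repeat("g", 2))
        assert not rep.group("g").reliable

    def test_recovers_known_coefficients_within_3se(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 0.4, 200)
        y = 0.05 + 1.8 * x + rng.normal(0, 0.01, 200)
        rep = group_regression(x, y, np.repeat("g", 200))
        row = rep.group("g")
        se = np.sqrt(row.sigma2 / ((x - x.mean()) ** 2).sum())
        assert abs(row.slope - 1.8) < 3 * se


class TestMeanOverestimation:
    def test_unbiased_is_zero(self):
        t = np.array([0.3, 0.4])
        assert mean_overestimation(t, t) == 0.0

    def test_hand_example(self):
        assert mean_overestimation([0.6, 0.3], [0.5, 0.25]) == pytest.approx(0.2)

    def test_proportional_bias(self):
        t = np.array([0.2, 0.3, 0.4])
        assert mean_overestimation(1.3 * t, t) == pytest.approx(0.3)

    def test_zero_true_excluded_with_warning(self):
        with pytest.warns(RuntimeWarning):
            v = mean_overestimation([0.6, 0.5], [0.5, 0.0])
        assert v == pytest.approx(0.2)

    def test_slope_minus_one_consistency(self):
        """For y = b*x (zero intercept), mean overestimation equals b - 1."""
        x = np.linspace(0.1, 0.5, 20)
        y = 1.4 * x
        rep = group_regression(x, y, np.repeat("g", 20))
        assert rep.group("g").slope - 1 == pytest.approx(
            mean_overestimation(y, x), abs=1e-9)


def _result_from_dosage(dosage, typed=None):
    dosage = np.asarray(dosage, dtype=float)
    S, N = dosage.shape
    typed = np.zeros((S, N), bool) if typed is None else typed
    post = np.repeat(dosage / 2.0, 2, axis=1)
    return ImputationResult(post, dosage.copy(),
                            np.round(dosage).astype(np.int8),
                            np.full(S, np.nan), typed, np.ones(S, bool),
                            np.arange(S))


class TestPerAnimalAccuracy:
    def _truth(self, col):
        from tests.conftest import make_genotypes
        return make_genotypes(np.asarray(col).reshape(-1, 1), ["A"])

    def test_perfect_imputation(self):
        truth = self._truth([0, 1, 2, 1])
        res = _result_from_dosage(np.array([[0.], [1.], [2.], [1.]]))
        assert per_animal_accuracy(truth, res)["r"].iloc[0] == pytest.approx(1.0)

    def test_systematic_flip_anticorrelated(self):
        truth = self._truth([0, 1, 2, 1])
        res = _result_from_dosage(np.array([[2.], [1.], [0.], [1.]]))
        assert per_animal_accuracy(truth, res)["r"].iloc[0] == pytest.approx(-1.0)

    def test_textbook_pearson_oracle(self):
        t = np.array([0, 1, 2, 1], dtype=float)
        m = np.array([0.2, 1.0, 1.8, 0.6])
        expect = (((t - t.mean()) * (m - m.mean())).sum()
                  / np.sqrt(((t - t.mean()) ** 2).sum()
                            * ((m - m.mean()) ** 2).sum()))
        truth = self._truth(t.astype(int))
        res = _result_from_dosage(m.reshape(-1, 1))
        assert per_animal_accuracy(truth, res)["r"].iloc[0] == pytest.approx(
            expect, abs=1e-12)

    def test_typed_sites_excluded(self):
        truth = self._truth([0, 1, 2, 1])
        typed = np.array([[True], [True], [False], [False]])
        res = _result_from_dosage(np.array([[0.], [1.], [2.], [1.]]), typed)
        assert per_animal_accuracy(truth, res)["n_sites"].iloc[0] == 2

    def test_zero_variance_reported_missing(self):
        truth = self._truth([1, 1, 1, 1])
        res = _result_from_dosage(np.array([[0.2], [1.0], [1.8], [0.6]]))
        out = per_animal_accuracy(truth, res)
        assert np.isnan(out["r"].iloc[0])
        assert out["reason"].iloc[0] == "zero variance"


@pytest.fixture(scope="module")
def scenario():
    model = PopulationModel(n_populations=3, drift_F=0.2, n_sites=500,
                            seed=21)
    # dense map (0.01 cM between sites) so copying states persist between
    # typed scaffold sites even for small reference panels
    data = simulate_dataset(model, 10, span_cm=5.0)
    mask = design_array(data.genotypes, "P1")
    return data, mask


class TestLeaveOneOut:
    def test_duplicate_individuals_impute_each_other(self, scenario):
        data, mask = scenario
        # each panel member has an "identical twin" still in the reduced panel
        twin = data.haplotypes.subset_individuals(np.array([0, 0, 10, 10]))
        twin.samples = np.array(["t1", "t2", "t3", "t4"], dtype=object)
        from ascbias.reference_panels import ReferencePanel
        panel = ReferencePanel(np.arange(4), twin.samples,
                               twin.populations, "randSamp", {"m": 4}, 0)
        out = leave_one_out(twin, mask, panel,
                            ImputerConfig(error_rate=1e-6))
        assert (out["r"] > 0.99).all()

    def test_one_per_population_has_no_same_pop_proxy(self, scenario):
        data, mask = scenario
        panel = sample_reference("allPop", {"k": 1}, data.genotypes, seed=5)
        out = leave_one_out(data.haplotypes, mask, panel)
        assert not out["same_pop_remaining"].any()

    def test_deep_population_imputes_better_than_singleton(self, scenario):
        data, mask = scenario
        # 5 reference individuals from P1, one from P2
        idx = np.concatenate([data.genotypes.individuals_of("P1")[:5],
                              data.genotypes.individuals_of("P2")[:1]])
        from ascbias.reference_panels import ReferencePanel
        panel = ReferencePanel(idx, data.genotypes.samples[idx],
                               data.genotypes.populations[idx],
                               "randSamp", {"m": 6}, 0)
        out = leave_one_out(data.haplotypes, mask, panel)
        deep = out[out["population"] == "P1"]["r"].median()
        shallow = out[out["population"] == "P2"]["r"].iloc[0]
        assert out[out["population"] == "P1"]["same_pop_remaining"].all()
        assert deep > shallow

    def test_panel_of_one_rejected(self, scenario):
        data, mask = scenario
        from ascbias.reference_panels import ReferencePanel
        panel = ReferencePanel(np.array([0]), data.genotypes.samples[:1],
                               data.genotypes.populations[:1],
                               "randSamp", {"m": 1}, 0)
        with pytest.raises(ValueError):
            leave_one_out(data.haplotypes, mask, panel)
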