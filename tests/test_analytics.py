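"""Trinomial theory: probability vectors, signal strengths, distributions."""

import math

import numpy as np
import pytest

from crossmatch.analytics import (
    CombinationCounts,
    ProbabilityTriple,
    combination_probabilities,
    default_c_grid,
    default_rho_grid,
    expected_surface,
    expected_value,
    operator_distribution,
    sd_surfaces,
    signal_strength_correlation,
    signal_strength_generalized,
    signal_strength_matching,
    trinomial_pmf,
)
from crossmatch.stimulus import ParameterError


def closed_form_k2(c, rho):
    return rho / 4 * (rho * c**2 + 2 * c + rho**3 - 3 * rho + 2)


class TestProbabilityVectors:
    def test_matched_vector(self):
        assert combination_probabilities(1.0, 0.25, True) == (0.25, 0.0, 0.75)
        assert combination_probabilities(0.0, 0.5, False) == (0.125, 0.125, 0.75)

    def test_zero_density_is_all_background(self):
        for c in (-1.0, 0.3, 1.0):
            for at in (True, False):
                assert combination_probabilities(c, 0.0, at) == (0.0, 0.0, 1.0)

    @pytest.mark.parametrize("c,rho", [(2.0, 0.5), (0.0, -0.1), (0.0, 1.5)])
    def test_out_of_range_rejected(self, c, rho):
        with pytest.raises(ParameterError):
            combination_probabilities(c, rho, True)

    def test_vectors_sum_to_one_on_grid(self):
        for c in default_c_grid():
            for rho in default_rho_grid():
                for at in (True, False):
                    p = combination_probabilities(c, rho, at)
                    assert abs(sum(p) - 1.0) < 1e-12


class TestExpectedValues:
    def test_correlation_peak_and_baseline(self):
        assert expected_value("correlation", 1.0, 0.25, True) == pytest.approx(0.25)
        assert expected_value("correlation", 0.7, 0.4, False) == pytest.approx(0.0)

    def test_matching_anticorrelated_peak_is_zero(self):
        for rho in (0.1, 0.5, 1.0):
            assert expected_value("matching", -1.0, rho, True) == 0.0

    def test_matching_baseline(self):
        assert expected_value("matching", 0.0, 0.25, False) == pytest.approx(0.03125)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            expected_value("energy", 0.0, 0.5, True)


class TestSignalStrengths:
    def test_correlation_is_separable_product(self):
        assert signal_strength_correlation(0.5, 0.25) == pytest.approx(0.125)
        assert signal_strength_correlation(1, 1) == 1.0

    def test_correlation_odd_symmetry_exact(self):
        c = default_c_grid()
        rho = default_rho_grid()
        cc, rr = np.meshgrid(c, rho)
        assert np.array_equal(
            signal_strength_correlation(-cc, rr), -signal_strength_correlation(cc, rr)
        )

    def test_matching_zero_contour_is_c_equals_rho_minus_one(self):
        for rho in default_rho_grid():
            assert signal_strength_matching(rho - 1.0, rho) == pytest.approx(0.0, abs=1e-15)

    def test_matching_peak_density_at_half(self):
        rho = np.linspace(0.0, 1.0, 2001)
        s = signal_strength_matching(0.0, rho)
        assert rho[np.argmax(s)] == pytest.approx(0.5)

    def test_anticorrelated_strength_decreases_with_density(self):
        rho = default_rho_grid()
        s = signal_strength_matching(-1.0, rho)
        assert np.allclose(s, -(rho**2) / 2)
        assert np.all(np.diff(s) < 0)


class TestGeneralized:
    def test_k1_equals_original_matching_on_grid(self):
        for c in default_c_grid()[::4]:
            for rho in default_rho_grid()[::4]:
                assert signal_strength_generalized(c, rho, 1) == pytest.approx(
                    signal_strength_matching(c, rho), abs=1e-12
                )

    def test_k2_matches_closed_form_on_grid(self):
        for c in default_c_grid():
            for rho in default_rho_grid():
                assert abs(
                    signal_strength_generalized(c, rho, 2) - closed_form_k2(c, rho)
                ) <= 1e-12

    def test_infinite_window_is_rectified_correlation(self):
        assert signal_strength_generalized(-1.0, 0.25, math.inf) == 0.0
        assert signal_strength_generalized(0.5, 0.5, "inf") == pytest.approx(0.25)

    def test_converges_to_rectified_correlation(self):
        """S_G(k) approaches [c rho]+ with k; decrease is monotone from k=8 on."""
        for c, rho in [(-1.0, 0.25), (-0.5, 0.6), (0.0, 0.5), (0.4, 0.8)]:
            limit = max(c * rho, 0.0)
            dist = [
                abs(signal_strength_generalized(c, rho, k) - limit)
                for k in (1, 2, 8, 32, 256)
            ]
            assert dist[-1] < 0.021
            assert dist[2] >= dist[3] >= dist[4]

    def test_invalid_window_size_rejected(self):
        with pytest.raises(ParameterError):
            signal_strength_generalized(0.0, 0.5, 0)


class TestTrinomial:
    def test_certain_category(self):
        assert trinomial_pmf(CombinationCounts(5, 0, 0), ProbabilityTriple(1, 0, 0)) == 1.0

    def test_against_direct_factorial_formula(self):
        n = CombinationCounts(1, 1, 0)
        p = ProbabilityTriple(0.5, 0.25, 0.25)
        direct = (
            math.factorial(2) / (math.factorial(1) * math.factorial(1) * math.factorial(0))
            * 0.5 * 0.25
        )
        assert trinomial_pmf(n, p) == pytest.approx(direct)
        assert direct == 0.25

    def test_normalization_k10(self):
        p = ProbabilityTriple(0.3, 0.2, 0.5)
        total = sum(
            trinomial_pmf(CombinationCounts(m, r, 10 - m - r), p)
            for m in range(11)
            for r in range(11 - m)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            trinomial_pmf(CombinationCounts(-1, 1, 2), ProbabilityTriple(0.3, 0.3, 0.4))
        with pytest.raises(ParameterError):
            ProbabilityTriple(0.5, 0.6, 0.2).validate()


class TestOperatorDistribution:
    def test_zero_density_point_mass(self):
        for model in ("correlation", "matching"):
            d = operator_distribution(model, 0.5, 0.0, 16, True)
            assert d.support.tolist() == [0.0]
            assert d.probabilities.tolist() == [1.0]
            assert d.interval == (0.0, 0.0)

    @pytest.mark.parametrize("model", ["correlation", "matching"])
    @pytest.mark.parametrize("c,rho,at", [(0.0, 0.5, True), (-0.6, 0.3, True), (0.2, 0.8, False)])
    def test_mean_consistent_with_expected_value(self, model, c, rho, at):
        d = operator_distribution(model, c, rho, 64, at)
        assert d.mean() == pytest.approx(expected_value(model, c, rho, at), abs=1e-9)
        assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matching_sd_is_binomial_closed_form(self):
        # p_m = 0.5 at c=0, rho=1, matched window; SD = sqrt(p(1-p)/k) = 0.5/32
        d = operator_distribution("matching", 0.0, 1.0, 1024, True)
        assert d.sd() == pytest.approx(0.5 / 32, abs=1e-12)

    def test_interval_mass_at_least_95(self):
        d = operator_distribution("correlation", 0.2, 0.5, 128, True)
        lo, hi = d.interval
        inside = (d.support >= lo) & (d.support <= hi)
        assert d.probabilities[inside].sum() >= 0.95
        # each excluded tail holds at most 2.5%
        assert d.probabilities[d.support < lo].sum() <= 0.025 + 1e-12
        assert d.probabilities[d.support > hi].sum() <= 0.025 + 1e-12


class TestSdSurface:
    def test_zero_density_row_is_zero(self):
        surfs = sd_surfaces(
            ["correlation"], c_grid=[0.0], rho_grid=[0.0], n_patterns=10, n_runs=1, seed=0
        )
        assert surfs["correlation"].values.tolist() == [[0.0]]

    def test_sd_scales_inversely_with_window_side(self):
        """Halving the window side (quartering k) doubles the SD."""
        kwargs = dict(c_grid=[0.0], rho_grid=[1.0], n_patterns=1500, n_runs=2, seed=42)
        big = sd_surfaces(["correlation"], k=1024, **kwargs)["correlation"].max()
        small = sd_surfaces(["correlation"], k=256, **kwargs)["correlation"].max()
        assert small / big == pytest.approx(2.0, rel=0.08)

    def test_seed_reproducible(self):
        kwargs = dict(c_grid=[0.5], rho_grid=[0.5], n_patterns=100, n_runs=2, seed=9)
        a = sd_surfaces(["matching"], **kwargs)["matching"].values
        b = sd_surfaces(["matching"], **kwargs)["matching"].values
        assert np.array_equal(a, b)


def test_expected_surface_round_trip(tmp_path):
    surf = expected_surface("matching")
    path = tmp_path / "surface.csv"
    surf.save(path)
    import pandas as pd

    table = pd.read_csv(path)
    expected = signal_strength_matching(table["correlation"], table["density"])
    assert np.allclose(table["value"], expected, atol=1e-12)
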