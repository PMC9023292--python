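"""Renewal-scheme kinetics: probabilities, optimum, mappings, correlation."""

import math

import numpy as np
import pytest

from degencode.kinetics import (
    EnergyVolumeTables,
    KineticParams,
    ModernParams,
    k_minus_from_dg,
    k_pep_from_volume,
    mean_elongation_time,
    modern_mean_time,
    modern_rate,
    optimal_k_minus,
    optimal_k_minus_numeric,
    p_pep,
    simulate_elongation,
    volume_correlation,
)
from degencode.synthetic import TableSpec, make_energy_volume_tables


class TestPPep:
    @pytest.mark.parametrize(
        "k_minus,k_pep,expected", [(1.0, 1.0, 0.5), (3.0, 1.0, 0.25)]
    )
    def test_values(self, k_minus, k_pep, expected):
        assert p_pep(k_minus, k_pep) == pytest.approx(expected)

    def test_limit_no_dissociation(self):
        assert p_pep(1e-12, 1.0) == pytest.approx(1.0)

    def test_monotonicity(self):
        grid = np.logspace(-2, 2, 20)
        probs = [p_pep(km, 1.0) for km in grid]
        assert all(a > b for a, b in zip(probs, probs[1:]))
        probs_up = [p_pep(1.0, kp) for kp in grid]
        assert all(a < b for a, b in zip(probs_up, probs_up[1:]))
        assert all(0 < p < 1 for p in probs)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("inf")])
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            p_pep(bad, 1.0)


class TestMeanTime:
    def test_symmetric_unit_rates(self):
        assert mean_elongation_time(KineticParams(1.0, 1.0, 1.0)) == pytest.approx(4.0)

    def test_divergence_at_both_extremes(self):
        ref = mean_elongation_time(KineticParams(1.0, 1.0, 1.0))
        slow_release = mean_elongation_time(KineticParams(1.0, 1e-6, 1.0))
        never_reacts = mean_elongation_time(KineticParams(1.0, 1e6, 1.0))
        assert slow_release > 1e5 * ref and never_reacts > 1e5 * ref

    def test_unique_interior_minimum_on_log_grid(self):
        grid = np.logspace(-3, 3, 121)
        times = np.array(
            [mean_elongation_time(KineticParams(2.0, km, 0.5)) for km in grid]
        )
        i_min = int(times.argmin())
        assert 0 < i_min < len(grid) - 1
        diffs = np.sign(np.diff(times))
        assert (diffs[: i_min] <= 0).all() and (diffs[i_min:] >= 0).all()


class TestOptimum:
    @pytest.mark.parametrize("k_arr,k_pep,expected", [(1.0, 1.0, 1.0), (4.0, 1.0, 2.0)])
    def test_closed_form(self, k_arr, k_pep, expected):
        assert optimal_k_minus(k_arr, k_pep) == pytest.approx(expected)

    def test_numeric_agrees_on_log_grid(self):
        for k_arr in np.logspace(-2, 2, 10):
            for k_pep in np.logspace(-2, 2, 10):
                closed = optimal_k_minus(k_arr, k_pep)
                numeric = optimal_k_minus_numeric(k_arr, k_pep)
                assert numeric == pytest.approx(closed, rel=1e-6)

    def test_optimum_beats_flanks(self):
        k_arr, k_pep = 3.0, 0.7
        star = optimal_k_minus(k_arr, k_pep)
        t_star = mean_elongation_time(KineticParams(k_arr, star, k_pep))
        for factor in (0.01, 100.0):
            assert (
                mean_elongation_time(KineticParams(k_arr, star * factor, k_pep))
                > t_star
            )

    def test_matching_arrival_recovers_k_pep(self):
        # the ancestral optimum k- = k_pep emerges when arrival matches chemistry
        assert optimal_k_minus(0.37, 0.37) == pytest.approx(0.37)


class TestModernScheme:
    def test_adds_accommodation_time(self):
        early = mean_elongation_time(KineticParams(1.0, 1.0, 1.0))
        modern = modern_mean_time(ModernParams(1.0, 1.0, 1.0, k_acc=2.0))
        assert modern == pytest.approx(early + 0.5)

    def test_unit_rates_give_five_seconds(self):
        res = modern_rate(ModernParams(1.0, 1.0, 1.0, k_acc=1.0))
        assert res.mean_time == pytest.approx(5.0)
        assert res.rate == pytest.approx(0.2)

    def test_fast_accommodation_limit(self):
        early = mean_elongation_time(KineticParams(1.0, 1.0, 1.0))
        assert modern_mean_time(
            ModernParams(1.0, 1.0, 1.0, k_acc=1e12)
        ) == pytest.approx(early)

    def test_ptc_levelled_k_pep(self):
        res = modern_rate(ModernParams(1.0, 1.0, 0.1, k_acc=1.0, k_pep_prime=1.0))
        assert res.mean_time == pytest.approx(5.0)


class TestEnergyMapping:
    tables = EnergyVolumeTables(dg0={"x": -1.0}, volume={"x": 100.0}, k0_off=2.0)

    def test_zero_energy_gives_prefactor(self):
        assert k_minus_from_dg(0.0, self.tables) == pytest.approx(2.0)

    def test_unit_exponent(self):
        assert k_minus_from_dg(-self.tables.rt, self.tables) == pytest.approx(
            2.0 * math.exp(-1)
        )

    def test_ddg_ratio(self):
        ratio = k_minus_from_dg(-1.0, self.tables) / k_minus_from_dg(0.0, self.tables)
        assert ratio == pytest.approx(math.exp(-1.0 / 0.616))
        assert ratio == pytest.approx(0.197, abs=0.001)

    def test_monotone_and_rescaling_equivariant(self):
        dgs = np.linspace(-3, 1, 9)
        ks = [k_minus_from_dg(dg, self.tables) for dg in dgs]
        assert all(a < b for a, b in zip(ks, ks[1:]))
        doubled = EnergyVolumeTables(
            dg0={"x": -1.0}, volume={"x": 100.0}, rt=2 * 0.616, k0_off=2.0
        )
        assert k_minus_from_dg(-2.0, doubled) == pytest.approx(
            k_minus_from_dg(-1.0, self.tables)
        )

    def test_rt_validation(self):
        with pytest.raises(ValueError, match="RT"):
            EnergyVolumeTables(dg0={"x": 0.0}, volume={"x": 1.0}, rt=0.0)

    def test_k_pep_volume_monotone_decreasing(self):
        vols = np.linspace(60, 230, 8)
        ks = [k_pep_from_volume(v, self.tables) for v in vols]
        assert all(a > b for a, b in zip(ks, ks[1:]))


class TestVolumeCorrelation:
    def test_perfect_log_linear_relation(self):
        tables = make_energy_volume_tables(TableSpec(n=20, noise_sd=0.0, seed=5))
        res = volume_correlation(tables)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_noisy_relation_recovered(self):
        # noise sd chosen so the population pearson r is 0.8 given the
        # uniform(60, 230) volume spread and slope 0.01
        signal_sd = 0.01 * (230 - 60) / math.sqrt(12)
        noise_sd = signal_sd * math.sqrt(1 / 0.8**2 - 1)
        tables = make_energy_volume_tables(TableSpec(n=20, noise_sd=noise_sd, seed=11))
        res = volume_correlation(tables)
        assert res.pearson_r == pytest.approx(0.8, abs=0.15)

    def test_exclusions_reported_separately(self):
        tables = make_energy_volume_tables(TableSpec(n=20, noise_sd=0.0, seed=5))
        res = volume_correlation(tables, exclusions=["asn", "arg", "trp"])
        assert set(res.excluded) == {"asn", "arg", "trp"}
        assert res.n == 17
        assert res.spearman_rho == pytest.approx(1.0)

    def test_constant_volume_degenerate(self):
        tables = EnergyVolumeTables(
            dg0={"a": -1.0, "b": -2.0, "c": -3.0},
            volume={"a": 100.0, "b": 100.0, "c": 100.0},
        )
        res = volume_correlation(tables)
        assert res.degenerate and math.isnan(res.spearman_rho)

    def test_insufficient_overlap(self):
        tables = EnergyVolumeTables(
            dg0={"a": -1.0, "b": -2.0, "c": -3.0},
            volume={"a": 1.0, "b": 2.0, "c": 3.0},
        )
        with pytest.raises(ValueError, match="at least 3"):
            volume_correlation(tables, exclusions=["a"])


class TestStochasticCrossCheck:
    def test_event_simulation_matches_closed_form(self):
        params = KineticParams(1.4, 0.9, 1.1)
        sim = simulate_elongation(params, n_events=30_000, seed=42)
        expected = mean_elongation_time(params)
        assert abs(sim.mean_time - expected) < 3 * sim.sem

    def test_reproducible_given_seed(self):
        params = KineticParams(1.0, 1.0, 1.0)
        a = simulate_elongation(params, n_events=500, seed=7)
        b = simulate_elongation(params, n_events=500, seed=7)
        assert a == b
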