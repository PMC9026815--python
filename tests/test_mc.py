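import dataclasses
import math

import numpy as np
import pytest

from chiradsorb import (
    LatticeState,
    MCSettings,
    ModelParams,
    equilibrate_and_measure,
    exact_enumeration,
    isotherm_scan,
    metropolis_sweep,
    snapshot,
    surface_ee,
)
from chiradsorb.mc import (
    IsothermResult,
    read_snapshot_csv,
    write_snapshot_csv,
)

from conftest import random_lattice


class TestMCSettings:
    def test_defaults(self):
        s = MCSettings()
        assert s.burn_in_sweeps == 2000
        assert s.measure_sweeps == 5000
        assert s.batches == 20

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"burn_in_sweeps": -1},
            {"measure_sweeps": 0},
            {"sample_interval": 0},
            {"batches": 5},
            {"measure_sweeps": 15, "batches": 20},
            {"measure_sweeps": 100, "sample_interval": 10, "batches": 20},
            {"init_mode": "fixed_ee"},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MCSettings(**kwargs)


class TestMetropolisSweep:
    def test_infinite_temperature_limit_gives_fair_spins(self):
        # exch = 0, h = 0: every flip accepted, sites become iid fair +/-1
        p = ModelParams(temperature=460.0)
        lat = LatticeState.all_d(20)
        rng = np.random.default_rng(5)
        means = []
        for _ in range(200):
            metropolis_sweep(lat, p, rng)
            means.append(surface_ee(lat))
        # mean over 200 sweeps of 400 iid fair sites: SE ~ 1/sqrt(200*400)
        assert abs(np.mean(means[20:])) < 0.02

    def test_rejects_enantiopure_gas(self):
        p = ModelParams(temperature=460.0, gas_ee=1.0)
        with pytest.raises(ValueError, match="gas_ee"):
            metropolis_sweep(LatticeState.all_d(4), p, np.random.default_rng(0))

    def test_frozen_at_zero_temperature_limit(self):
        # large coupling, ordered start: no flip is ever accepted in practice
        p = ModelParams(temperature=1.0, exch_energy=1e5)
        lat = LatticeState.all_d(5)
        metropolis_sweep(lat, p, np.random.default_rng(0))
        assert surface_ee(lat) == 1.0


class TestEquilibrateAndMeasure:
    def test_reproducibility_bit_identical(self, asp_params, fast_settings):
        a = equilibrate_and_measure(asp_params, fast_settings, side=16)
        b = equilibrate_and_measure(asp_params, fast_settings, side=16)
        assert a == b

    def test_different_seeds_differ(self, asp_params, fast_settings):
        a = equilibrate_and_measure(asp_params, fast_settings, side=16)
        b = equilibrate_and_measure(
            asp_params, dataclasses.replace(fast_settings, seed=99), side=16
        )
        assert a.mean_ees != b.mean_ees

    def test_fair_spin_case(self, racemic_params):
        # exch = 0, h = 0: racemic within errors, homochiral fraction ~ 1/2
        s = MCSettings(seed=2, burn_in_sweeps=100, measure_sweeps=1000)
        est = equilibrate_and_measure(racemic_params, s, side=32)
        assert abs(est.mean_ees) < 3 * est.std_error_ees + 1e-3
        assert est.mean_homochiral_fraction == pytest.approx(0.5, abs=0.01)

    def test_racemic_above_tc(self, asp_params):
        s = MCSettings(seed=3, burn_in_sweeps=300, measure_sweeps=1500)
        est = equilibrate_and_measure(asp_params, s, side=32)
        assert abs(est.mean_ees) <= 3 * est.std_error_ees + 0.01

    @pytest.mark.parametrize("eeg,sign", [(1.0, 1.0), (-1.0, -1.0)])
    def test_enantiopure_short_circuit(self, eeg, sign, fast_settings):
        p = ModelParams(temperature=460.0, exch_energy=2310.0, gas_ee=eeg)
        est = equilibrate_and_measure(p, fast_settings, side=10)
        assert est.mean_ees == sign
        assert est.mean_abs_ees == 1.0
        assert est.std_error_ees == 0.0
        assert est.mean_homochiral_fraction == 1.0
        assert est.n_samples == 0

    def test_estimate_invariants(self, asp_params, fast_settings):
        est = equilibrate_and_measure(asp_params, fast_settings, side=16)
        assert abs(est.mean_ees) <= est.mean_abs_ees <= 1.0
        assert est.std_error_ees >= 0.0
        assert est.n_samples == fast_settings.n_samples

    def test_ordered_start_below_tc(self):
        p = ModelParams(temperature=250.0, exch_energy=2310.0)
        s = MCSettings(seed=4, burn_in_sweeps=200, measure_sweeps=600, init_mode="all_L")
        est = equilibrate_and_measure(p, s, side=24)
        assert est.mean_ees < -0.9  # stays in the ordered L branch

    def test_zero_field_sign_symmetric_ensemble(self, asp_params):
        # distribution of mean_ees over seeds is symmetric about 0
        s = MCSettings(seed=0, burn_in_sweeps=100, measure_sweeps=300, batches=10)
        vals = [
            equilibrate_and_measure(
                asp_params, dataclasses.replace(s, seed=k), side=16
            ).mean_ees
            for k in range(12)
        ]
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals)) < 4 * se + 0.02


class TestSmallLatticeOracle:
    """Long-run MC averages against exact enumeration (quick versions;
    the acceptance suite runs the full three-regime comparison)."""

    def test_finite_field_4x4(self):
        p = ModelParams(temperature=460.0, exch_energy=2310.0, gas_ee=0.2)
        ex = exact_enumeration(p, 4)
        s = MCSettings(seed=7, burn_in_sweeps=1000, measure_sweeps=40_000, sample_interval=4)
        est = equilibrate_and_measure(p, s, side=4)
        assert abs(est.mean_ees - ex.ees) < 3 * est.std_error_ees
        assert abs(est.mean_homochiral_fraction - ex.homochiral_fraction) \
            < 3 * est.std_error_homochiral_fraction


class TestIsothermScan:
    def test_endpoints_exact(self, asp_params, fast_settings):
        res = isotherm_scan(asp_params, [-1.0, 0.0, 1.0], fast_settings, side=10)
        assert res.estimates[0].mean_ees == -1.0
        assert res.estimates[2].mean_ees == 1.0
        assert abs(res.estimates[1].mean_ees) < 0.5

    def test_rejects_duplicates(self, asp_params, fast_settings):
        with pytest.raises(ValueError, match="duplicate|increasing"):
            isotherm_scan(asp_params, [0.0, 0.0, 0.5], fast_settings, side=10)

    def test_rejects_out_of_range(self, asp_params, fast_settings):
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            isotherm_scan(asp_params, [-2.0, 0.0], fast_settings, side=10)

    def test_independent_site_identity(self, racemic_params):
        # exch = 0: ees(eeg) = eeg at every grid point (quick version)
        s = MCSettings(seed=5, burn_in_sweeps=50, measure_sweeps=500)
        grid = [-0.5, 0.0, 0.5]
        res = isotherm_scan(racemic_params, grid, s, side=32)
        for g, est in zip(grid, res.estimates):
            assert abs(est.mean_ees - g) < 3 * est.std_error_ees + 5e-3

    def test_monotone_in_eeg(self, asp_params):
        s = MCSettings(seed=6, burn_in_sweeps=300, measure_sweeps=900)
        grid = [-0.5, -0.1, 0.0, 0.1, 0.5]
        res = isotherm_scan(asp_params, grid, s, side=32)
        ees = res.ees_mean
        tol = 3 * max(e.std_error_ees for e in res.estimates)
        assert all(b - a > -tol for a, b in zip(ees, ees[1:]))

    def test_reproducible(self, asp_params, fast_settings):
        a = isotherm_scan(asp_params, [-0.3, 0.3], fast_settings, side=12)
        b = isotherm_scan(asp_params, [-0.3, 0.3], fast_settings, side=12)
        assert a.ees_mean.tolist() == b.ees_mean.tolist()

    def test_csv_round_trip(self, asp_params, fast_settings, tmp_path):
        res = isotherm_scan(asp_params, [-0.3, 0.0, 0.3], fast_settings, side=12)
        path = tmp_path / "iso.csv"
        res.to_csv(path)
        back = IsothermResult.from_csv(path)
        assert back.eeg == res.eeg
        for x, y in zip(back.estimates, res.estimates):
            assert x.mean_ees == y.mean_ees
            assert x.std_error_ees == y.std_error_ees
            assert x.mean_energy_per_site == y.mean_energy_per_site


class TestSnapshot:
    def test_all_d_3x3(self):
        assert snapshot(LatticeState.all_d(3)) == [["D"] * 3] * 3

    def test_round_trip(self, tmp_path):
        lat = random_lattice(8, 42)
        path = tmp_path / "lat.csv"
        write_snapshot_csv(lat, path)
        assert read_snapshot_csv(path) == lat

    def test_label_counts_match_surface_ee(self):
        lat = random_lattice(9, 9)
        rows = snapshot(lat)
        n_d = sum(r.count("D") for r in rows)
        n_l = sum(r.count("L") for r in rows)
        assert (n_d - n_l) / (n_d + n_l) == pytest.approx(surface_ee(lat))


class TestKernelFallback:
    def test_pure_python_fallback_matches_compiled(self):
        # the numba kernel and its .py_func draw the same MT19937 stream
        from chiradsorb.mc import _run_chain

        if not hasattr(_run_chain, "py_func"):
            pytest.skip("numba not active; fallback is the implementation")
        chi_a = random_lattice(8, 0).chirality.copy()
        chi_b = chi_a.copy()
        args = (30, 60, 1, 0.05, 0.3, 987654)
        mags_a, pairs_a = _run_chain(chi_a, *args)
        mags_b, pairs_b = _run_chain.py_func(chi_b, *args)
        assert np.array_equal(chi_a, chi_b)
        assert np.array_equal(mags_a, mags_b)
        assert np.array_equal(pairs_a, pairs_b)
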