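"""Permeation model: reweighting edge cases, hopping rates, KMC physics
and current-voltage relations."""
import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ionpath as ip
from ionpath import GridAxis, Hill, KMCConfig, PermeationProfile
from ionpath.constants import thermal_energy, voltage_to_kcal
from ionpath.kmc import _boundary_rates


def _flat_profile(M=25, span=12.0, D=0.5):
    return PermeationProfile(
        z=np.linspace(0, span, M), free_energy=np.zeros(M), diffusion=D
    )


def _barrier_profile(height, M=31, span=12.0, sigma=0.8, D=0.5):
    z = np.linspace(0, span, M)
    W = height * np.exp(-((z - span / 2) ** 2) / (2 * sigma**2))
    return PermeationProfile(z=z, free_energy=W, diffusion=D)


def _stationary_current(rates, config):
    """Deterministic oracle: exact stationary net flux of the open channel
    by linear algebra (states: empty + every bin)."""
    enter_in, enter_out, exit_in, exit_out = _boundary_rates(rates, config)
    M = rates.n_bins
    n = M + 1  # state 0 = empty, state i+1 = bin i
    Q = np.zeros((n, n))

    def add(i, j, rate):
        Q[i, j] += rate
        Q[i, i] -= rate

    add(0, 1, enter_in)
    add(0, M, enter_out)
    add(1, 0, exit_in)
    add(M, 0, exit_out)
    for i in range(M - 1):
        add(i + 1, i + 2, rates.up[i])
        add(i + 2, i + 1, rates.down[i])
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    flux = pi[M] * exit_out - pi[0] * enter_out  # net flow into the outside
    return 1.602176634e-19 * flux * 1e9 * 1e12  # events/ns -> pA


class TestReweighting:
    def _frames(self, rng, n=4000):
        z = rng.uniform(0.0, 10.0, n)
        return z[:, None], z

    def test_zero_bias_equals_plain_histogram(self, rng):
        cv, z = self._frames(rng)
        bins = GridAxis("z", 0, 10, 20)
        prof = ip.reweight_to_z(cv, z, [], bins, burn_in=0.0)
        kT = thermal_energy(310.0)
        hist, _ = np.histogram(z, bins=bins.edges)
        expected = -kT * np.log(hist)
        expected -= expected.min()
        np.testing.assert_allclose(prof.free_energy, expected, atol=1e-10)

    def test_constant_bias_is_shift_invariant(self, rng):
        cv, z = self._frames(rng)
        bins = GridAxis("z", 0, 10, 20)
        base = ip.reweight_to_z(cv, z, [], bins, burn_in=0.0)
        # a very wide hill is constant over the sampled range
        wide = [Hill((5.0,), (1e6,), 2.0, time=1.0)]
        shifted = ip.reweight_to_z(cv, z, wide, bins, burn_in=0.0, mode="final")
        np.testing.assert_allclose(shifted.free_energy, base.free_energy, atol=1e-6)

    def test_degenerate_weights_raise_with_ess(self, rng):
        cv, z = self._frames(rng, n=200)
        # a narrow enormous hill makes a handful of frames dominate
        spike = [Hill((5.0,), (0.05,), 50.0, time=1.0)]
        with pytest.raises(ValueError, match="sample size"):
            ip.reweight_to_z(cv, z, spike, GridAxis("z", 0, 10, 20),
                             burn_in=0.0, mode="final")

    def test_burn_in_validation(self, rng):
        cv, z = self._frames(rng, n=100)
        with pytest.raises(ValueError, match="burn_in"):
            ip.reweight_to_z(cv, z, [], GridAxis("z", 0, 10, 10), burn_in=1.0)


class TestBuildRates:
    def test_flat_profile_rates_are_d_over_delta_squared(self):
        prof = _flat_profile(M=13, span=12.0, D=0.5)
        rates = ip.build_rates(prof, voltage=0.0)
        expected = 0.5 / prof.spacing**2
        np.testing.assert_allclose(rates.up, expected)
        np.testing.assert_allclose(rates.down, expected)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), voltage=st.floats(-120.0, 120.0))
    def test_detailed_balance_exact(self, seed, voltage):
        rng = np.random.default_rng(seed)
        prof = PermeationProfile(
            z=np.linspace(0, 10, 21), free_energy=rng.uniform(0, 5, 21), diffusion=0.5
        )
        rates = ip.build_rates(prof, voltage=voltage)
        ratio = rates.up / rates.down
        expected = np.exp(-np.diff(rates.tilted) / rates.kT)
        np.testing.assert_allclose(ratio, expected, rtol=1e-12)

    def test_voltage_tilt_magnitude(self):
        """-40 mV tilts the profile by 0.9224 kcal/mol across the span
        (40 mV x 23.06 kcal/mol per eV)."""
        prof = _flat_profile()
        rates = ip.build_rates(prof, voltage=-40.0)
        drop = rates.tilted[0] - rates.tilted[-1]
        assert drop == pytest.approx(-0.9224, abs=2e-4)
        assert voltage_to_kcal(40.0) == pytest.approx(0.9224, abs=2e-4)

    def test_non_uniform_grid_rejected(self):
        z = np.array([0.0, 1.0, 2.5, 3.0])
        with pytest.raises(ValueError, match="uniform"):
            PermeationProfile(z=z, free_energy=np.zeros(4))


class TestRunKMC:
    def test_zero_entry_rate_raises(self):
        rates = ip.build_rates(_flat_profile(), 0.0)
        cfg = KMCConfig(conc_in=0.0, conc_out=0.0, total_time=0.1)
        with pytest.raises(ValueError, match="zero total rate"):
            ip.run_kmc(rates, cfg)

    def test_reproducible_per_seed(self):
        rates = ip.build_rates(_flat_profile(), -40.0)
        cfg = KMCConfig(voltage=-40.0, total_time=1.0, seed=11)
        a = ip.run_kmc(rates, cfg)
        b = ip.run_kmc(rates, cfg)
        assert (a.n_outward, a.n_inward) == (b.n_outward, b.n_inward)

    def test_closed_chain_occupancy_is_boltzmann(self):
        """Chi-square test of sojourn-time fractions against the Boltzmann
        weights of the tilted profile."""
        prof = PermeationProfile(
            z=np.linspace(0, 6, 13),
            free_energy=1.5 * np.sin(np.linspace(0, np.pi, 13)),
            diffusion=0.5,
        )
        rates = ip.build_rates(prof, voltage=25.0)
        times, states = ip.run_closed_chain(
            rates, n_events=400_000, start=0, seed=17, record_states=True
        )
        frac = times / times.sum()
        pi = np.exp(-rates.tilted / rates.kT)
        pi /= pi.sum()
        # the time fractions themselves agree closely with Boltzmann
        assert np.max(np.abs(frac - pi)) < 0.01
        # chi-square on visits subsampled beyond the chain's mixing time
        # against the embedded-chain stationary law pi_i * k_i_total
        k_tot = np.zeros(pi.size)
        k_tot[:-1] += rates.up
        k_tot[1:] += rates.down
        pi_visit = pi * k_tot
        pi_visit /= pi_visit.sum()
        # odd stride: nearest-neighbor moves alternate state parity every
        # event, so an even stride would sample a single parity class
        sub = states[::999]
        counts = np.bincount(sub, minlength=pi.size)
        chi2, p = stats.chisquare(counts, pi_visit * sub.size)
        assert p > 0.05

    def test_current_matches_stationary_oracle(self):
        """Stochastic current agrees with the exact stationary flux of the
        same chain computed by linear algebra."""
        prof = _barrier_profile(2.0)
        rates = ip.build_rates(prof, voltage=-60.0)
        cfg = KMCConfig(voltage=-60.0, total_time=40.0, seed=23)
        exact = _stationary_current(rates, cfg)
        currents = [
            ip.run_kmc(rates, dataclasses.replace(cfg, seed=s)).current
            for s in range(12)
        ]
        mean = np.mean(currents)
        se = np.std(currents, ddof=1) / math.sqrt(len(currents))
        assert abs(mean - exact) < max(3 * se, 0.15 * abs(exact))

    def test_current_antisymmetry(self):
        """I(V) is antisymmetric under V -> -V with swapped concentrations
        and a mirrored profile."""
        rng = np.random.default_rng(5)
        W = rng.uniform(0, 2, 21)
        z = np.linspace(0, 10, 21)
        prof = PermeationProfile(z=z, free_energy=W, diffusion=0.5)
        mirror = PermeationProfile(z=z, free_energy=W[::-1], diffusion=0.5)

        def mean_current(profile, V, cin, cout):
            rates = ip.build_rates(profile, voltage=V)
            vals = [
                ip.run_kmc(rates, KMCConfig(voltage=V, conc_in=cin, conc_out=cout,
                                            total_time=20.0, seed=s)).current
                for s in range(10)
            ]
            return np.mean(vals), np.std(vals, ddof=1) / math.sqrt(10)

        i1, se1 = mean_current(prof, 50.0, 100.0, 300.0)
        i2, se2 = mean_current(mirror, -50.0, 300.0, 100.0)
        assert abs(i1 + i2) < 3 * math.hypot(se1, se2) + 0.02


class TestFirstPassage:
    def test_vectorized_kmc_matches_exact_discrete_mfpt(self):
        M = 15
        z = np.linspace(0, 4, M)
        W = 2.0 * np.exp(-((z - 2.0) ** 2) / (2 * 0.5**2))
        prof = PermeationProfile(z=z, free_energy=W, diffusion=0.5)
        rates = ip.build_rates(prof, 0.0)
        exact = ip.mfpt_discrete(rates, 0, M - 1)
        fpt = ip.first_passage_times(rates, 0, M - 1, n_replicas=4000, seed=9)
        se = fpt.std(ddof=1) / math.sqrt(fpt.size)
        assert abs(fpt.mean() - exact) < 3 * se

    def test_discrete_mfpt_converges_to_quadrature(self):
        for M, tol in ((41, 0.05), (161, 0.02)):
            z = np.linspace(0, 4, M)
            W = 3.0 * np.exp(-((z - 2.0) ** 2) / (2 * 0.5**2))
            prof = PermeationProfile(z=z, free_energy=W, diffusion=0.5)
            rates = ip.build_rates(prof, 0.0)
            ratio = ip.mfpt_discrete(rates, 0, M - 1) / ip.mfpt_quadrature(prof, 0, 4)
            assert ratio == pytest.approx(1.0, abs=tol)

    def test_mirrored_direction_agrees(self):
        M = 15
        rng = np.random.default_rng(1)
        prof = PermeationProfile(
            z=np.linspace(0, 4, M), free_energy=rng.uniform(0, 2, M), diffusion=0.5
        )
        rates = ip.build_rates(prof, 0.0)
        forward = ip.mfpt_discrete(rates, 0, M - 1)
        mirrored = PermeationProfile(
            z=prof.z, free_energy=prof.free_energy[::-1], diffusion=0.5
        )
        back = ip.mfpt_discrete(ip.build_rates(mirrored, 0.0), 0, M - 1)
        assert back == pytest.approx(
            ip.mfpt_discrete(rates, M - 1, 0), rel=1e-10
        )
        assert forward > 0 and back > 0


class TestIVCurve:
    def test_translocation_arithmetic(self):
        """51 net outward events in 40 us are 0.204 pA; at -40 mV the chord
        conductance is 5.1 pS."""
        from ionpath.kmc import KMCResult

        res = KMCResult(n_outward=51, n_inward=0, simulated_time=40.0, voltage=-40.0)
        assert res.current == pytest.approx(0.204, abs=0.001)
        assert abs(res.chord_conductance) == pytest.approx(5.1, abs=0.03)

    def test_chord_equals_slope_for_linear_iv(self):
        prof = _flat_profile(M=15, span=8.0, D=1.0)
        cfg = KMCConfig(total_time=40.0, seed=3)
        table, slope = ip.iv_curve(prof, [-60.0, -30.0, 30.0, 60.0], cfg)
        chords = table["chord_pS"].to_numpy()
        assert np.all(np.isfinite(chords))
        assert np.allclose(chords, slope, rtol=0.35)

    def test_zero_voltage_chord_flagged(self):
        prof = _flat_profile(M=15, span=8.0, D=1.0)
        cfg = KMCConfig(total_time=5.0, seed=3)
        table, _ = ip.iv_curve(prof, [-30.0, 0.0, 30.0], cfg)
        row = table[table["voltage_mV"] == 0.0]
        assert np.isnan(row["chord_pS"].iloc[0])

    def test_slope_conductance_matches_stationary_oracle(self):
        """Slope conductance of the flat-profile symmetric channel agrees
        with the exact diffusion-limited stationary flux within 15 %."""
        prof = _flat_profile(M=15, span=8.0, D=1.0)
        cfg = KMCConfig(total_time=80.0, seed=7)
        table, slope = ip.iv_curve(prof, [-40.0, -20.0, 20.0, 40.0], cfg)
        exact = []
        for v in (-40.0, -20.0, 20.0, 40.0):
            rates = ip.build_rates(prof, voltage=v)
            exact.append(_stationary_current(rates, dataclasses.replace(cfg, voltage=v)))
        slope_exact = np.polyfit([-40.0, -20.0, 20.0, 40.0], exact, 1)[0] * 1e3
        assert slope == pytest.approx(slope_exact, rel=0.15)

    def test_fewer_than_two_voltages_rejected(self):
        with pytest.raises(ValueError, match="two voltages"):
            ip.iv_curve(_flat_profile(), [10.0], KMCConfig(total_time=1.0))


class TestConductanceTrend:
    def test_conductance_increases_as_barrier_drops(self):
        """Lowering the dominant barrier 8 -> 6 -> 3 kcal/mol at fixed D
        strictly increases the KMC conductance magnitude."""
        results = []
        for height, total in ((8.0, 2000.0), (6.0, 400.0), (3.0, 40.0)):
            prof = _barrier_profile(height, sigma=0.7)
            rates = ip.build_rates(prof, voltage=-120.0)
            cfg = KMCConfig(voltage=-120.0, total_time=total, seed=3)
            res = ip.run_kmc(rates, cfg)
            results.append(abs(res.chord_conductance))
        assert results[0] < results[1] < results[2]
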