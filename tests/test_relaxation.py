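"""15N relaxation: decay fits, R1rho->R2 correction, NOE, Monte Carlo, tau_c."""

import math

import numpy as np
import pytest

from idrkit.relaxation import (
    R1_TIME_GRID,
    R1RHO_TIME_GRID,
    DecaySeries,
    SpectrometerContext,
    SpinLockParams,
    analyze_relaxation,
    fit_exponential_decay,
    het_noe,
    monte_carlo_errors,
    r1rho_from_r2,
    r2_from_r1rho,
    rates_for_tumbling_time,
    tumbling_time,
)
from idrkit.synthetic import gen_decay_series

CTX_700 = SpectrometerContext(700.0)


class TestDecayFit:
    def test_noiseless_recovery_on_sampling_grid(self):
        y = 100.0 * np.exp(-2.0 * R1_TIME_GRID)
        fit = fit_exponential_decay(DecaySeries(1, R1_TIME_GRID, y))
        assert fit.rate == pytest.approx(2.0, rel=1e-8)
        assert fit.i0 == pytest.approx(100.0, rel=1e-8)

    def test_constant_intensities_fit_rate_zero(self):
        fit = fit_exponential_decay(DecaySeries(1, R1_TIME_GRID, np.full(10, 50.0)))
        assert fit.rate == pytest.approx(0.0, abs=1e-10)

    def test_noisy_rate_within_three_sigma(self):
        rng = np.random.default_rng(11)
        y = 100.0 * np.exp(-5.0 * R1RHO_TIME_GRID) + rng.normal(0, 1, R1RHO_TIME_GRID.shape)
        fit = fit_exponential_decay(DecaySeries(1, R1RHO_TIME_GRID, y, noise_sd=1.0))
        assert abs(fit.rate - 5.0) < 3 * fit.rate_error

    def test_negative_rate_flagged_not_clipped(self):
        y = 100.0 * np.exp(0.5 * R1_TIME_GRID)  # growing "decay"
        fit = fit_exponential_decay(DecaySeries(1, R1_TIME_GRID, y))
        assert fit.negative_rate and fit.rate < 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            DecaySeries(1, np.array([0.1, 0.2]), np.array([1.0, 0.5]))


class TestR2Correction:
    def test_on_resonance_identity(self):
        assert r2_from_r1rho(1.2, 4.0, SpinLockParams(1433.0, 0.0)) == pytest.approx(4.0)

    def test_unit_tilt(self):
        # offset equal to the spin-lock strength: tan(theta) = 1, R2 = 2*R1rho - R1
        assert r2_from_r1rho(1.0, 2.0, SpinLockParams(1433.0, 1433.0)) == pytest.approx(3.0)

    def test_printed_formula_at_typical_offset(self):
        r2 = r2_from_r1rho(1.2, 4.0, SpinLockParams(1433.0, 500.0))
        assert r2 == pytest.approx(4.341, abs=5e-4)

    def test_inverts_rotating_frame_average_randomized(self):
        """R2 -> R1rho (tilt average) -> R2 is the identity over random inputs."""
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            r1 = rng.uniform(0.5, 3.0)
            r2 = rng.uniform(r1, 15.0)
            sl = SpinLockParams(1433.0, rng.uniform(-2000.0, 2000.0))
            r1rho = r1rho_from_r2(r1, r2, sl)
            assert r2_from_r1rho(r1, r1rho, sl) == pytest.approx(r2, rel=1e-12)

    def test_monotone_in_offset(self):
        offsets = np.linspace(0, 2000, 40)
        up = [r2_from_r1rho(1.0, 3.0, SpinLockParams(1433.0, o)) for o in offsets]
        down = [r2_from_r1rho(3.0, 1.0, SpinLockParams(1433.0, o)) for o in offsets]
        flat = [r2_from_r1rho(2.0, 2.0, SpinLockParams(1433.0, o)) for o in offsets]
        assert np.all(np.diff(up) > 0) and np.all(np.diff(down) < 0)
        assert np.allclose(flat, 2.0)

    def test_large_tilt_warns(self):
        with pytest.warns(UserWarning):
            r2_from_r1rho(1.0, 2.0, SpinLockParams(100.0, 500.0))


class TestHetNoe:
    def test_basic_ratio_and_zero_noise(self):
        noe, sigma, ok = het_noe(50.0, 100.0, 0.0)
        assert (noe, sigma, ok) == (0.5, 0.0, True)
        assert het_noe(70.0, 70.0, 0.0)[0] == 1.0

    def test_propagated_error_hand_value(self):
        noe, sigma, _ = het_noe(40.0, 100.0, 2.0)
        assert sigma == pytest.approx(0.4 * math.sqrt((2 / 40) ** 2 + (2 / 100) ** 2), rel=1e-12)
        assert sigma == pytest.approx(0.02154, abs=1e-5)

    def test_reference_near_noise_flagged(self):
        assert het_noe(1.0, 5.0, 2.0)[2] is False


class TestMonteCarlo:
    def _series(self, sd):
        return DecaySeries(1, R1_TIME_GRID, 100.0 * np.exp(-2.0 * R1_TIME_GRID), noise_sd=sd)

    def test_zero_noise_gives_zero_sd(self):
        assert monte_carlo_errors(self._series(0.0), 20, seed=1) == 0.0

    def test_same_seed_reproducible(self):
        a = monte_carlo_errors(self._series(1.0), 50, seed=42)
        b = monte_carlo_errors(self._series(1.0), 50, seed=42)
        assert a == b

    def test_mc_sd_matches_asymptotic_covariance(self):
        series = self._series(1.0)
        mc = monte_carlo_errors(series, 100, seed=7)
        rng = np.random.default_rng(5)
        noisy = DecaySeries(1, R1_TIME_GRID,
                            series.intensities + rng.normal(0, 1.0, R1_TIME_GRID.shape), 1.0)
        asym = fit_exponential_decay(noisy).rate_error
        assert mc / asym == pytest.approx(1.0, abs=0.5)


class TestTumblingTime:
    def test_radicand_zero_boundary(self):
        tau, flag = tumbling_time(1.2, 1.2 * 7 / 6, CTX_700)
        assert tau == pytest.approx(0.0, abs=1e-15) and flag == "ok"

    def test_chain_average_rates_give_published_range(self):
        tau, _ = tumbling_time(1.2, 4.7, CTX_700)
        assert tau == pytest.approx(4.56e-9, rel=1e-3)

    def test_inverse_field_scaling(self):
        tau700, _ = tumbling_time(1.2, 4.7, CTX_700)
        tau1400, _ = tumbling_time(1.2, 4.7, SpectrometerContext(1400.0))
        assert tau1400 == pytest.approx(tau700 / 2, rel=1e-12)

    def test_fast_limit_flagged(self):
        tau, flag = tumbling_time(2.0, 2.0, CTX_700)
        assert tau is None and flag == "fast-limit"

    def test_monotone_in_rate_ratio_and_roundtrip(self):
        ratios = np.linspace(7 / 6, 10, 25)
        taus = [tumbling_time(1.0, r, CTX_700)[0] for r in ratios]
        assert np.all(np.diff(taus) > 0)
        for tau in (1e-9, 4.5e-9, 10e-9):
            r2 = rates_for_tumbling_time(tau, 1.2, CTX_700)
            back, _ = tumbling_time(1.2, r2, CTX_700)
            assert back == pytest.approx(tau, rel=1e-12)


def test_pipeline_helix_residues_rank_above_linker():
    """Synthetic two-helix R1/R1rho profiles: the pipeline's R2 and tau_c keep
    the helix residues above the interhelical linker, as in the experimental
    relaxation profiles."""
    residues = range(1, 61)
    helix = set(range(10, 21)) | set(range(40, 51))
    r1_true = {r: 1.3 if r in helix else 1.15 for r in residues}
    r2_true = {r: 6.5 if r in helix else 3.8 for r in residues}
    sl = SpinLockParams(1433.0, 300.0)
    r1rho_true = {r: r1rho_from_r2(r1_true[r], r2_true[r], sl) for r in residues}
    r1_series, _ = gen_decay_series(r1_true, time_grid=R1_TIME_GRID, noise_sd=0.3, seed=21)
    rho_series, _ = gen_decay_series(r1rho_true, time_grid=R1RHO_TIME_GRID, noise_sd=0.3, seed=22)
    result = analyze_relaxation(
        r1_series, rho_series, CTX_700, offsets_hz={r: 300.0 for r in residues},
        n_mc_runs=20, seed=5)
    recs = {r.residue: r for r in result.records}
    helix_r2 = np.mean([recs[r].r2 for r in helix])
    linker_r2 = np.mean([recs[r].r2 for r in residues if r not in helix])
    assert helix_r2 > linker_r2 + 1.0
    helix_tau = np.mean([recs[r].tau_c for r in helix if recs[r].tau_c])
    linker_tau = np.mean([recs[r].tau_c for r in residues if r not in helix and recs[r].tau_c])
    assert helix_tau > linker_tau
    # the two chain-average conventions agree closely on a uniform-ish chain
    assert result.mean_tau_c == pytest.approx(result.tau_c_of_mean_rates, rel=0.1)
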