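"""Backbone 15N relaxation analysis for disordered proteins.

Covers monoexponential decay fitting for R1 and R1rho, conversion of R1rho
to R2 with the spin-lock tilt-angle (off-resonance) correction, steady-state
heteronuclear NOE ratios with error propagation, Monte-Carlo rate errors,
and extraction of an effective residue-specific rotational correlation time
from the R2/R1 ratio.

Conventions: the spin-lock tilt angle is theta = arctan(2*pi*dnu / (gammaN*B1))
= arctan(dnu/nu1), so that on resonance (dnu = 0) theta = 0 and R2 = R1rho.
The R2/R1 correlation-time estimate assumes the heteronuclear spectral
density is dominated by a single effective reorientation time; exchange
broadening is not corrected for.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

#: |gamma_N / gamma_H| for 15N (unitless frequency ratio)
GAMMA_RATIO_N_H = 0.10136767

#: gyromagnetic ratio of 15N, rad s^-1 T^-1 (magnitude)
GAMMA_N = 2.7126e7

#: sampling grids used for the longitudinal and rotating-frame decays (s)
R1_TIME_GRID = np.array([0.040, 0.088, 0.136, 0.192, 0.288, 0.392, 0.592, 0.688, 0.792, 0.992])
R1RHO_TIME_GRID = np.array([0.030, 0.060, 0.120, 0.150, 0.180, 0.210])

#: default spin-lock field strength, Hz
DEFAULT_SPINLOCK_HZ = 1433.0


class FitError(RuntimeError):
    """Decay fit failed to converge; carries initializer diagnostics."""


@dataclass(frozen=True)
class SpectrometerContext:
    """Static field context; nitrogen frequency is derived from the proton one."""

    proton_frequency_mhz: float = 700.0

    @property
    def nitrogen_frequency_hz(self) -> float:
        return self.proton_frequency_mhz * 1e6 * GAMMA_RATIO_N_H


@dataclass(frozen=True)
class SpinLockParams:
    """Spin-lock field strength and per-residue resonance offset."""

    spin_lock_hz: float = DEFAULT_SPINLOCK_HZ  # nu1 = |gammaN*B1|/2pi
    offset_hz: float = 0.0                     # dnu

    def __post_init__(self) -> None:
        if self.spin_lock_hz <= 0:
            raise ValueError("spin-lock strength must be positive")

    @property
    def tilt(self) -> float:
        """Tilt angle theta = arctan(dnu/nu1), radians in [0, pi/2)."""
        return math.atan(abs(self.offset_hz) / self.spin_lock_hz)


@dataclass
class DecaySeries:
    """One residue's intensity decay I(t)."""

    residue: int
    times: np.ndarray       # s, strictly increasing
    intensities: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size < 3:
            raise ValueError(f"residue {self.residue}: need >= 3 time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"residue {self.residue}: time points must be strictly increasing")


@dataclass
class DecayFit:
    i0: float
    rate: float            # s^-1
    covariance: np.ndarray  # 2x2 for (i0, rate)
    negative_rate: bool = False

    @property
    def rate_error(self) -> float:
        return float(math.sqrt(max(self.covariance[1, 1], 0.0)))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Deterministic initializer: I0 = max intensity, R from a log-linear fit."""
    i0 = float(np.max(y))
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        r0 = -float(slope)
    else:
        r0 = 1.0 / (t[-1] - t[0])
    return i0, r0


def fit_exponential_decay(series: DecaySeries) -> DecayFit:
    """Least-squares fit of I(t) = I0 * exp(-R * t)."""
    t, y = series.times, series.intensities
    i0_0, r0 = _initial_guess(t, y)

    def model(t, i0, r):
        return i0 * np.exp(-r * t)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, t, y, p0=[i0_0, r0], maxfev=10000)
    except RuntimeError as exc:
        raise FitError(
            f"residue {series.residue}: decay fit did not converge (init I0={i0_0:.4g}, R={r0:.4g})"
        ) from exc
    i0, r = float(popt[0]), float(popt[1])
    return DecayFit(i0=i0, rate=r, covariance=np.asarray(pcov), negative_rate=r < 0)


def r2_from_r1rho(r1: float, r1rho: float, spinlock: SpinLockParams) -> float:
    """Off-resonance correction: R2 = R1rho + (R1rho - R1) * tan^2(theta)."""
    if not (math.isfinite(r1) and math.isfinite(r1rho)):
        raise ValueError("R1 and R1rho must be finite")
    ratio = abs(spinlock.offset_hz) / spinlock.spin_lock_hz
    if ratio > 3:
        warnings.warn(
            f"offset/spin-lock ratio {ratio:.2f} > 3: tilt correction unreliable",
            stacklevel=2,
        )
    tan2 = math.tan(spinlock.tilt) ** 2
    return r1rho + (r1rho - r1) * tan2


def r1rho_from_r2(r1: float, r2: float, spinlock: SpinLockParams) -> float:
    """Forward model R1rho = R1 sin^2(theta) + R2 cos^2(theta) (for simulation)."""
    th = spinlock.tilt
    return r1 * math.sin(th) ** 2 + r2 * math.cos(th) ** 2


def het_noe(i_sat: float, i_ref: float, noise_sd: float = 0.0) -> tuple[float, float, bool]:
    """Heteronuclear NOE = I_sat/I_ref with propagated error.

    Returns (NOE, sigma, reliable); the record is flagged unreliable when the
    reference intensity is within 3 noise sd of zero.
    """
    if i_ref == 0:
        raise ZeroDivisionError("reference intensity is zero")
    noe = i_sat / i_ref
    if noise_sd == 0 or i_sat == 0:
        sigma = 0.0 if i_sat != 0 else abs(noise_sd / i_ref)
    else:
        sigma = abs(noe) * math.sqrt((noise_sd / i_sat) ** 2 + (noise_sd / i_ref) ** 2)
    reliable = abs(i_ref) > 3 * noise_sd
    return noe, sigma, reliable


def monte_carlo_errors(series: DecaySeries, n_runs: int = 100, seed: int = 0) -> float:
    """Monte-Carlo rate uncertainty: refit noise-perturbed copies of the decay.

    Gaussian perturbations with sd = series.noise_sd are added independently
    to every intensity; the standard deviation of the refitted rates is
    returned.  Reproducible for a fixed seed.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    rng = np.random.default_rng(seed)
    rates = []
    failures = 0
    for _ in range(n_runs):
        perturbed = series.intensities + rng.normal(0.0, series.noise_sd, size=series.intensities.shape)
        try:
            fit = fit_exponential_decay(
                DecaySeries(series.residue, series.times, perturbed, series.noise_sd)
            )
            rates.append(fit.rate)
        except FitError:
            failures += 1
    if failures > 0.2 * n_runs:
        raise FitError(f"residue {series.residue}: {failures}/{n_runs} Monte-Carlo refits failed")
    return float(np.std(rates, ddof=1))


def tumbling_time(r1: float, r2: float, ctx: SpectrometerContext) -> tuple[float | None, str]:
    """Effective rotational correlation time from the R2/R1 ratio.

    tau_c = sqrt(6*R2/R1 - 7) / (4*pi*nu_N); returns (tau_c_seconds, reason)
    where tau_c is None with reason 'fast-limit' when the radicand is
    negative (R2/R1 < 7/6).
    """
    if r1 <= 0:
        raise ValueError("R1 must be positive")
    radicand = 6.0 * r2 / r1 - 7.0
    if radicand < 0:
        return None, "fast-limit"
    return math.sqrt(radicand) / (4.0 * math.pi * ctx.nitrogen_frequency_hz), "ok"


def rates_for_tumbling_time(tau_c: float, r1: float, ctx: SpectrometerContext) -> float:
    """Invert the tau_c formula: the R2 implied by (tau_c, R1) at this field."""
    x = tau_c * 4.0 * math.pi * ctx.nitrogen_frequency_hz
    return r1 * (x * x + 7.0) / 6.0


@dataclass
class RelaxationRecord:
    residue: int
    r1: float | None = None
    r1_err: float | None = None
    r1rho: float | None = None
    r1rho_err: float | None = None
    r2: float | None = None
    r2_err: float | None = None
    noe: float | None = None
    noe_err: float | None = None
    tau_c: float | None = None
    tau_c_flag: str = ""


@dataclass
class RelaxationResult:
    records: list[RelaxationRecord]
    mean_tau_c: float | None            # mean of per-residue tau_c
    tau_c_of_mean_rates: float | None   # tau_c computed from chain-mean R1, R2

    def to_records(self) -> list[dict]:
        return [vars(r).copy() for r in self.records]


def analyze_relaxation(
    r1_decays: list[DecaySeries],
    r1rho_decays: list[DecaySeries],
    ctx: SpectrometerContext,
    spin_lock_hz: float = DEFAULT_SPINLOCK_HZ,
    offsets_hz: dict[int, float] | None = None,
    noe_intensities: dict[int, tuple[float, float, float]] | None = None,
    n_mc_runs: int = 100,
    seed: int = 0,
) -> RelaxationResult:
    """Full per-residue pipeline: fit decays, correct R1rho to R2, NOEs, tau_c.

    ``offsets_hz`` maps residue -> spin-lock resonance offset (default 0);
    ``noe_intensities`` maps residue -> (I_sat, I_ref, noise_sd).  Monte-Carlo
    errors use sub-seeds derived deterministically from ``seed``.
    """
    offsets_hz = offsets_hz or {}
    records: dict[int, RelaxationRecord] = {}

    def rec(residue: int) -> RelaxationRecord:
        return records.setdefault(residue, RelaxationRecord(residue=residue))

    ss = np.random.SeedSequence(seed)
    sub = iter(ss.generate_state(2 * (len(r1_decays) + len(r1rho_decays)) + 2) % (2**31))

    for series in r1_decays:
        fit = fit_exponential_decay(series)
        r = rec(series.residue)
        r.r1 = fit.rate
        r.r1_err = (
            monte_carlo_errors(series, n_mc_runs, int(next(sub)))
            if series.noise_sd > 0 else fit.rate_error
        )
    for series in r1rho_decays:
        fit = fit_exponential_decay(series)
        r = rec(series.residue)
        r.r1rho = fit.rate
        r.r1rho_err = (
            monte_carlo_errors(series, n_mc_runs, int(next(sub)))
            if series.noise_sd > 0 else fit.rate_error
        )
    for r in records.values():
        if r.r1 is not None and r.r1rho is not None:
            sl = SpinLockParams(spin_lock_hz, offsets_hz.get(r.residue, 0.0))
            r.r2 = r2_from_r1rho(r.r1, r.r1rho, sl)
            tan2 = math.tan(sl.tilt) ** 2
            if r.r1_err is not None and r.r1rho_err is not None:
                r.r2_err = math.sqrt(((1 + tan2) * r.r1rho_err) ** 2 + (tan2 * r.r1_err) ** 2)
            r.tau_c, r.tau_c_flag = tumbling_time(r.r1, r.r2, ctx)
    if noe_intensities:
        for residue, (i_sat, i_ref, sd) in noe_intensities.items():
            r = rec(residue)
            noe, sigma, reliable = het_noe(i_sat, i_ref, sd)
            r.noe, r.noe_err = noe, sigma
            if not reliable:
                r.tau_c_flag = (r.tau_c_flag + ";noe-unreliable").lstrip(";")

    taus = [r.tau_c for r in records.values() if r.tau_c is not None]
    mean_tau = float(np.mean(taus)) if taus else None
    both = [(r.r1, r.r2) for r in records.values() if r.r1 is not None and r.r2 is not None]
    tau_of_means = None
    if both:
        mr1 = float(np.mean([b[0] for b in both]))
        mr2 = float(np.mean([b[1] for b in both]))
        tau_of_means, _ = tumbling_time(mr1, mr2, ctx)
    ordered = [records[k] for k in sorted(records)]
    return RelaxationResult(records=ordered, mean_tau_c=mean_tau, tau_c_of_mean_rates=tau_of_means)
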