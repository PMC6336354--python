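"""1:1 binding analysis: SPR sensorgram kinetics, steady-state affinity,
and equilibrium isotherms with ligand depletion.

The kinetic model is the simple Langmuir bimolecular scheme A + B <-> AB
with association rate ka (M^-1 s^-1) and dissociation rate kd (s^-1):
during association at analyte concentration C the response follows
R(t) = Req * (1 - exp(-kobs*t)) with kobs = ka*C + kd and
Req = C*Rmax/(C + KD); after the analyte is washed out the response decays
as R(t_a) * exp(-kd*(t - t_a)).  KD = kd/ka throughout.

The equilibrium isotherm uses the depletion-exact quadratic solution for
the bound fraction of a labeled species at fixed total concentration L0
titrated with partner at total concentration T0, the regime in which
thermophoresis dose-response data are fitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import optimize, stats


@dataclass
class SensorgramCurve:
    concentration: float  # M
    times: np.ndarray     # s
    response: np.ndarray  # RU

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("sensorgram times must be strictly increasing")


@dataclass
class SensorgramSet:
    curves: list[SensorgramCurve]
    t_association_end: float  # s
    t_dissociation_end: float  # s

    def __post_init__(self) -> None:
        if self.t_association_end >= self.t_dissociation_end:
            raise ValueError("association must end before dissociation ends")

    def concentrations(self) -> np.ndarray:
        return np.array([c.concentration for c in self.curves])


@dataclass
class KineticFit:
    ka: float          # M^-1 s^-1
    kd: float          # s^-1
    rmax: float | np.ndarray  # RU (scalar if shared)
    ka_err: float
    kd_err: float
    kd_over_ka_err: float     # delta-method error on KD
    kobs: np.ndarray          # per curve
    req: np.ndarray           # per curve
    residual_sd: float
    warnings: list[str] = field(default_factory=list)

    @property
    def KD(self) -> float:
        return self.kd / self.ka


@dataclass
class IsothermData:
    labeled_concentration: float  # L0, M
    titrant: np.ndarray           # T0 series, M
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.titrant = np.asarray(self.titrant, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.labeled_concentration <= 0:
            raise ValueError("labeled concentration must be positive")


@dataclass
class EquilibriumFit:
    KD: float
    KD_err: float
    s_free: float
    s_bound: float
    fraction_bound: np.ndarray
    signal_to_noise: float
    low_confidence: bool = False


def kd_from_rates(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant KD = kd/ka (M)."""
    if ka <= 0:
        raise ValueError("ka must be positive")
    return kd / ka


def model_sensorgram(ka: float, kd: float, rmax: float, concentration: float,
                     times: np.ndarray, t_association_end: float) -> np.ndarray:
    """1:1 Langmuir response curve over association + dissociation phases."""
    if min(ka, kd, rmax, concentration) <= 0:
        raise ValueError("all model parameters must be positive")
    t = np.asarray(times, dtype=float)
    kobs = ka * concentration + kd
    req = concentration * rmax / (concentration + kd / ka)
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_association_end)))
    r_ta = req * (1.0 - math.exp(-kobs * t_association_end))
    dissoc = r_ta * np.exp(-kd * np.clip(t - t_association_end, 0.0, None))
    return np.where(t <= t_association_end, assoc, dissoc)


def _init_kinetic(data: SensorgramSet) -> tuple[float, float, float, list[str]]:
    """Deterministic initializer: kd from dissociation tails, ka from kobs vs C."""
    notes: list[str] = []
    ta = data.t_association_end
    slopes = []
    for c in data.curves:
        m = (c.times > ta) & (c.response > 0)
        if m.sum() >= 3:
            slopes.append(-np.polyfit(c.times[m], np.log(c.response[m]), 1)[0])
    kd0 = float(np.median(slopes)) if slopes else 1e-3
    if kd0 <= 0:
        notes.append("no dissociation decay detected; kd poorly identifiable")
        kd0 = 1e-6
    kobs0, conc, rmax0 = [], [], 0.0
    for c in data.curves:
        m = c.times <= ta
        t, y = c.times[m], c.response[m]
        ymax = y.max() if y.size else 0.0
        rmax0 = max(rmax0, ymax)
        try:
            popt, _ = optimize.curve_fit(
                lambda t, req, k: req * (1 - np.exp(-k * t)), t, y,
                p0=[max(ymax, 1e-9), max(kd0 * 2, 1e-3)], maxfev=5000)
            kobs0.append(popt[1]); conc.append(c.concentration)
        except RuntimeError:
            continue
    if len(kobs0) >= 2:
        slope = stats.linregress(conc, kobs0).slope
        ka0 = float(slope) if slope > 0 else kd0 / np.median(conc)
    else:
        ka0 = kd0 / np.median(data.concentrations())
        notes.append("association pre-fits failed; crude ka initializer")
    return max(ka0, 1e-6), max(kd0, 1e-9), max(rmax0, 1e-6), notes


def fit_kinetic_1to1(data: SensorgramSet, share_rmax: bool = True) -> KineticFit:
    """Global least-squares fit of ka, kd (and Rmax) over all concentrations.

    All points are weighted equally.  Non-identifiability (all concentrations
    far from KD, or no dissociation decay) is reported as a warning attached
    to the fit rather than an exception.
    """
    if len({c.concentration for c in data.curves}) < 2:
        raise ValueError("global kinetic fit needs >= 2 distinct concentrations")
    ka0, kd0, rmax0, notes = _init_kinetic(data)
    params = lmfit.Parameters()
    params.add("log_ka", value=math.log10(ka0), min=-6, max=12)
    params.add("log_kd", value=math.log10(kd0), min=-12, max=6)
    if share_rmax:
        params.add("log_rmax", value=math.log10(rmax0), min=-6, max=12)
    else:
        for i in range(len(data.curves)):
            params.add(f"log_rmax_{i}", value=math.log10(rmax0), min=-6, max=12)

    def residuals(p):
        ka, kd = 10 ** p["log_ka"].value, 10 ** p["log_kd"].value
        res = []
        for i, c in enumerate(data.curves):
            rmax = 10 ** (p["log_rmax"].value if share_rmax else p[f"log_rmax_{i}"].value)
            res.append(model_sensorgram(ka, kd, rmax, c.concentration, c.times,
                                        data.t_association_end) - c.response)
        return np.concatenate(res)

    result = lmfit.minimize(residuals, params, method="leastsq")
    if not result.success:
        raise RuntimeError(f"kinetic fit failed (init ka={ka0:.3g}, kd={kd0:.3g}, Rmax={rmax0:.3g})")
    ka = 10 ** result.params["log_ka"].value
    kd = 10 ** result.params["log_kd"].value
    if share_rmax:
        rmax = 10 ** result.params["log_rmax"].value
    else:
        rmax = np.array([10 ** result.params[f"log_rmax_{i}"].value for i in range(len(data.curves))])
    ln10 = math.log(10)
    ka_err = (result.params["log_ka"].stderr or 0.0) * ln10 * ka
    kd_err = (result.params["log_kd"].stderr or 0.0) * ln10 * kd
    # delta method on KD = kd/ka with the log-parameter covariance
    kd_over_ka_err = 0.0
    if result.covar is not None:
        names = list(result.var_names)
        ia, id_ = names.index("log_ka"), names.index("log_kd")
        var_log_kD = (result.covar[id_, id_] + result.covar[ia, ia] - 2 * result.covar[id_, ia])
        kd_over_ka_err = math.sqrt(max(var_log_kD, 0.0)) * ln10 * (kd / ka)
    conc = data.concentrations()
    KD = kd / ka
    warnings_ = list(notes)
    if conc.min() > 50 * KD or conc.max() < KD / 50:
        warnings_.append("all concentrations far from KD; affinity poorly identifiable")
    resid = residuals(result.params)
    return KineticFit(
        ka=ka, kd=kd, rmax=rmax, ka_err=ka_err, kd_err=kd_err,
        kd_over_ka_err=kd_over_ka_err,
        kobs=ka * conc + kd, req=conc * (np.atleast_1d(rmax)[0] if share_rmax else np.atleast_1d(rmax)) / (conc + KD),
        residual_sd=float(np.std(resid, ddof=min(len(resid) - 1, result.nvarys))),
        warnings=warnings_,
    )


def fit_steady_state(data: SensorgramSet, plateau_window: float = 20.0) -> tuple[float, float, dict]:
    """Steady-state affinity fit Req(C) = Rmax*C/(C + KD).

    Req is the mean response over the last ``plateau_window`` seconds of the
    association phase; curves whose response varies by more than 5% of its
    plateau mean inside the window are excluded with a warning.
    """
    ta = data.t_association_end
    req, conc, excluded = [], [], []
    for c in data.curves:
        m = (c.times >= ta - plateau_window) & (c.times <= ta)
        y = c.response[m]
        if y.size == 0 or (np.ptp(y) > 0.05 * abs(np.mean(y)) if np.mean(y) != 0 else True):
            excluded.append(c.concentration)
            continue
        req.append(float(np.mean(y)))
        conc.append(c.concentration)
    if len(set(conc)) < 2:
        raise ValueError("steady-state fit needs >= 2 plateaued concentrations")
    conc_a, req_a = np.array(conc), np.array(req)
    params = lmfit.Parameters()
    params.add("KD", value=float(np.median(conc_a)), min=0)
    params.add("Rmax", value=float(req_a.max() * 1.5), min=0)
    out = lmfit.minimize(
        lambda p: p["Rmax"].value * conc_a / (conc_a + p["KD"].value) - req_a, params, method="leastsq"
    )
    info = {
        "KD_err": out.params["KD"].stderr or 0.0,
        "Rmax": out.params["Rmax"].value,
        "Rmax_err": out.params["Rmax"].stderr or 0.0,
        "excluded_concentrations": excluded,
    }
    if excluded:
        warnings.warn(f"plateau criterion unmet for concentrations {excluded}", stacklevel=2)
    return out.params["KD"].value, out.params["Rmax"].value, info


def fraction_bound(titrant: np.ndarray, kd: float, labeled: float) -> np.ndarray:
    """Depletion-exact bound fraction of the labeled species.

    FB = ((L0+T0+KD) - sqrt((L0+T0+KD)^2 - 4*L0*T0)) / (2*L0); reduces to
    the hyperbolic T0/(T0+KD) as L0 -> 0.
    """
    t0 = np.asarray(titrant, dtype=float)
    s = labeled + t0 + kd
    disc = np.maximum(s * s - 4.0 * labeled * t0, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * labeled)


def fit_equilibrium_isotherm(data: IsothermData) -> EquilibriumFit:
    """Fit signal = S_free + (S_bound - S_free) * FB(T0; KD, L0) for KD and the plateaus."""
    t0, y = data.titrant, data.signal
    if t0.size < 8 or t0.max() / max(t0.min(), 1e-30) < 100:
        raise ValueError("need >= 8 points spanning at least a 100-fold titrant range")
    l0 = data.labeled_concentration
    params = lmfit.Parameters()
    params.add("log_KD", value=math.log10(np.median(t0)))
    params.add("s_free", value=float(y[np.argmin(t0)]))
    params.add("s_bound", value=float(y[np.argmax(t0)]))

    def residuals(p):
        fb = fraction_bound(t0, 10 ** p["log_KD"].value, l0)
        return p["s_free"].value + (p["s_bound"].value - p["s_free"].value) * fb - y

    out = lmfit.minimize(residuals, params, method="leastsq")
    kd = 10 ** out.params["log_KD"].value
    kd_err = (out.params["log_KD"].stderr or 0.0) * math.log(10) * kd
    fb = fraction_bound(t0, kd, l0)
    resid = residuals(out.params)
    resid_sd = float(np.std(resid, ddof=min(resid.size - 1, 3)))
    amp = abs(out.params["s_bound"].value - out.params["s_free"].value)
    return EquilibriumFit(
        KD=kd, KD_err=kd_err,
        s_free=out.params["s_free"].value, s_bound=out.params["s_bound"].value,
        fraction_bound=fb,
        signal_to_noise=amp / resid_sd if resid_sd > 0 else math.inf,
        low_confidence=resid_sd > 0 and amp < 3 * resid_sd,
    )
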