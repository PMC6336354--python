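"""Synthetic-data generators with attached ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes — population-weighted helix/coil chemical shifts, monoexponential
intensity decays on the experimental sampling grids, 1:1 Langmuir
sensorgrams over the experimental concentration ladder, depletion-corrected
binding isotherms (16-point 2-fold dilutions with a 10 nM labeled species),
run-and-pause particle tracks, and puncta-on-background images — and
returns a :class:`SyntheticTruth` carrying the generating parameters so
that recovery can be tested.  All randomness flows through an explicit
integer seed; regeneration with the same seed is bit-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import binding, relaxation
from .formats import ShiftEntry, ShiftTable
from .ssp import ReferenceShiftLibrary, load_reference_library
from .transport import Track

#: default analyte concentration ladder for sensorgram generation (M)
SPR_CONCENTRATIONS_M = (50e-6, 11e-6, 4.5e-6, 1.8e-6, 0.3e-6)

#: default isotherm design: 16-point 2-fold dilution with 10 nM labeled species
ISOTHERM_TOP_M = 42.5e-6
ISOTHERM_POINTS = 16
ISOTHERM_DILUTION = 2.0
LABELED_NM = 10.0

#: default frame intervals for track generation (s)
FAST_FRAME_INTERVAL_S = 0.2
SLOW_FRAME_INTERVAL_S = 5.0


@dataclass
class SyntheticTruth:
    generator: str
    seed: int
    params: dict = field(default_factory=dict)


def gen_idr_shifts(
    sequence: str,
    helix_population: np.ndarray,
    library: ReferenceShiftLibrary | None = None,
    noise_sd_ppm: float = 0.0,
    first_residue: int = 1,
    seed: int = 0,
) -> tuple[ShiftTable, SyntheticTruth]:
    """Population-weighted helix/coil shifts with Gaussian noise.

    For each residue and nucleus, delta_obs = delta_rc + population *
    helix_secondary + noise.  ``helix_population`` is the per-residue
    helical fraction in [0, 1]; prolines get no amide entries and glycines
    no CB.
    """
    pop = np.asarray(helix_population, dtype=float)
    if pop.shape != (len(sequence),):
        raise ValueError("helix_population must have one value per sequence position")
    if np.any((pop < 0) | (pop > 1)):
        raise ValueError("populations must lie in [0, 1]")
    if library is None:
        library = load_reference_library()
    rng = np.random.default_rng(seed)
    entries = []
    for i, aa in enumerate(sequence):
        resnum = first_residue + i
        for nuc in ("H", "N", "C", "CA", "CB"):
            if not library.covers(aa, nuc):
                continue
            shift = (library.rc[(aa, nuc)] + pop[i] * library.helix[(aa, nuc)]
                     + (rng.normal(0.0, noise_sd_ppm) if noise_sd_ppm > 0 else 0.0))
            entries.append(ShiftEntry(resnum, aa, nuc, shift))
    truth = SyntheticTruth("gen_idr_shifts", seed, {
        "sequence": sequence, "helix_population": pop.copy(),
        "noise_sd_ppm": noise_sd_ppm, "first_residue": first_residue,
    })
    return ShiftTable(entries), truth


def gen_decay_series(
    rates: dict[int, float],
    i0: float = 100.0,
    time_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[relaxation.DecaySeries], SyntheticTruth]:
    """Monoexponential decays I = I0*exp(-R*t) + noise, one per residue.

    The default time grid is the longitudinal-relaxation sampling schedule;
    pass :data:`idrkit.relaxation.R1RHO_TIME_GRID` for rotating-frame decays.
    """
    grid = relaxation.R1_TIME_GRID if time_grid is None else np.asarray(time_grid, dtype=float)
    rng = np.random.default_rng(seed)
    series = []
    for residue in sorted(rates):
        r = rates[residue]
        if r <= 0:
            raise ValueError(f"residue {residue}: rate must be positive")
        y = i0 * np.exp(-r * grid)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=grid.shape)
        series.append(relaxation.DecaySeries(residue, grid.copy(), y, noise_sd))
    truth = SyntheticTruth("gen_decay_series", seed, {
        "rates": dict(rates), "i0": i0, "time_grid": grid.copy(), "noise_sd": noise_sd,
    })
    return series, truth


def gen_sensorgrams(
    ka: float,
    kd: float,
    rmax: float = 100.0,
    concentrations=SPR_CONCENTRATIONS_M,
    t_association_end: float = 120.0,
    t_dissociation_end: float = 720.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[binding.SensorgramSet, SyntheticTruth]:
    """1:1 Langmuir sensorgrams over a concentration ladder, plus noise."""
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_dissociation_end + dt / 2, dt)
    curves = []
    for c in concentrations:
        r = binding.model_sensorgram(ka, kd, rmax, c, times, t_association_end)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=times.shape)
        curves.append(binding.SensorgramCurve(c, times.copy(), r))
    truth = SyntheticTruth("gen_sensorgrams", seed, {
        "ka": ka, "kd": kd, "rmax": rmax, "concentrations": tuple(concentrations),
        "noise_sd": noise_sd,
    })
    return binding.SensorgramSet(curves, t_association_end, t_dissociation_end), truth


def gen_isotherm(
    kd: float,
    labeled: float = LABELED_NM * 1e-9,
    top_concentration: float = ISOTHERM_TOP_M,
    n_points: int = ISOTHERM_POINTS,
    dilution_factor: float = ISOTHERM_DILUTION,
    s_free: float = 800.0,
    s_bound: float = 900.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[binding.IsothermData, SyntheticTruth]:
    """Depletion-exact equilibrium isotherm over a serial-dilution ladder."""
    rng = np.random.default_rng(seed)
    t0 = top_concentration / dilution_factor ** np.arange(n_points)
    fb = binding.fraction_bound(t0, kd, labeled)
    y = s_free + (s_bound - s_free) * fb
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    truth = SyntheticTruth("gen_isotherm", seed, {
        "KD": kd, "labeled": labeled, "top": top_concentration,
        "s_free": s_free, "s_bound": s_bound, "noise_sd": noise_sd,
    })
    return binding.IsothermData(labeled, t0, y), truth


#: run-and-pause state model: velocities (um/s) for the anterograde,
#: retrograde and paused states, and per-frame transition probabilities
DEFAULT_STATE_VELOCITIES = (1.2, -1.5, 0.0)
DEFAULT_TRANSITIONS = (
    (0.95, 0.005, 0.045),
    (0.005, 0.95, 0.045),
    (0.035, 0.035, 0.93),
)


def gen_tracks(
    n_tracks: int = 200,
    duration: float = 60.0,
    dt: float = FAST_FRAME_INTERVAL_S,
    velocities=DEFAULT_STATE_VELOCITIES,
    transitions=DEFAULT_TRANSITIONS,
    initial_distribution=None,
    position_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[Track], SyntheticTruth]:
    """Run-and-pause particle tracks from a discrete-state Markov motility model.

    States are (anterograde, retrograde, pause) with the given velocities;
    the per-frame transition matrix rows must sum to 1.  Positions are the
    integral of the state velocity, optionally with Gaussian localisation
    noise.  The truth records every track's state sequence.
    """
    P = np.asarray(transitions, dtype=float)
    if P.shape != (3, 3) or not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("transition matrix must be 3x3 with rows summing to 1")
    v = np.asarray(velocities, dtype=float)
    if initial_distribution is None:
        # stationary distribution of the chain
        w, vecs = np.linalg.eig(P.T)
        pi = np.real(vecs[:, np.argmin(np.abs(w - 1.0))])
        pi = np.abs(pi) / np.abs(pi).sum()
    else:
        pi = np.asarray(initial_distribution, dtype=float)
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / dt))
    tracks, state_seqs = [], []
    for tid in range(n_tracks):
        states = np.empty(n_frames, dtype=int)
        states[0] = rng.choice(3, p=pi)
        for k in range(1, n_frames):
            states[k] = rng.choice(3, p=P[states[k - 1]])
        pos = np.concatenate([[0.0], np.cumsum(v[states] * dt)])
        if position_noise_sd > 0:
            pos = pos + rng.normal(0.0, position_noise_sd, size=pos.shape)
        tracks.append(Track(tid, dt, pos))
        state_seqs.append(states)
    truth = SyntheticTruth("gen_tracks", seed, {
        "velocities": tuple(v), "transitions": P.copy(), "dt": dt,
        "state_sequences": state_seqs,
    })
    return tracks, truth


def gen_roi_image(
    shape: tuple[int, int] = (64, 64),
    background_level: float = 10.0,
    puncta=(),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray], SyntheticTruth]:
    """Gaussian puncta on a constant background, with per-punctum inner masks.

    Each punctum is (x, y, integrated_intensity, width_px); its rendered
    pixel values integrate to the requested intensity up to the Gaussian
    tail outside the image.  The returned masks are squares of half-width
    4*width centred on each punctum, which capture essentially the whole
    punctum when it is well inside the image.
    """
    rng = np.random.default_rng(seed)
    img = np.full(shape, float(background_level))
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    masks = []
    for (x, y, integral, width) in puncta:
        if not (0 <= x < shape[1] and 0 <= y < shape[0]):
            raise ValueError("punctum centre outside image")
        g = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * width ** 2))
        img += integral * g / g.sum()
        half = int(math.ceil(4 * width))
        mask = np.zeros(shape, dtype=bool)
        mask[max(0, int(y) - half):int(y) + half + 1,
             max(0, int(x) - half):int(x) + half + 1] = True
        masks.append(mask)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    truth = SyntheticTruth("gen_roi_image", seed, {
        "background": background_level, "puncta": tuple(puncta), "noise_sd": noise_sd,
    })
    return img, masks, truth

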