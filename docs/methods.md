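# Methods

## Scope and models

The package implements the quantitative layer of a transient-helix
characterisation of a disordered protein tail: chemical-shift secondary
structure propensity (SSP), backbone ¹⁵N relaxation, titration quenching
maps, 1:1 binding fits, CD unit conversion, and image-derived transport /
spindle statistics. Each stage has a matching synthetic-data generator
that carries its ground truth, and the test suite is built around
truth recovery under those generators.

## SSP scoring

Model: a two-state helix/coil ensemble in fast exchange, so the observed
secondary shift of every nucleus is the population-weighted helix
secondary shift, and the score is linear in helical population with the
endpoints +1 (full helix), −1 (full sheet), 0 (coil).

Per (residue, nucleus) the normalised propensity is p = s/|Δδ_α| when
s = sign(Δδ_α)·Δδ_obs ≥ 0 and p = s/|Δδ_β| otherwise; the residue score is
the weighted mean of p over a centred window (default W = 5 residues,
truncated at the chain ends) and all available nuclei, with weights
∝ |Δδ_ref|² so that the more shift-sensitive nuclei dominate. Missing
shifts are omitted, not imputed; a residue with no shifts in its window
gets no score. This is a deliberately simple SSP variant: neighbour-residue
corrections and multi-state deconvolution are out of scope, and parity
with any external SSP program is not claimed — the endpoint and linearity
semantics are the contract the tests enforce.

Re-referencing: chemical-shift referencing errors shift all carbons
coherently, so with re-referencing on, the CA and CB offsets are the
10%-trimmed mean of the raw secondary shifts over the whole chain
(trimming keeps a couple of short helical segments from dragging the
offset), and other nuclei are left untouched.

The reference table (packaged TSV) combines a standard random-coil shift
compilation with per-nucleus full-helix/full-sheet secondary shifts
(CA +2.8/−1.4, CO +2.1/−1.2, CB −0.5/+2.5, N −1.6/+2.2, Hᴺ −0.3/+0.45
ppm). Because generators and profiler share the library, tests are
insensitive to its absolute values; they check the score semantics, not
shift-prediction accuracy.

## ¹⁵N relaxation

Decays are fitted to I(t) = I₀e^(−Rt) by unweighted least squares with a
deterministic initialiser (I₀ = max intensity, R from a log-linear
regression on positive intensities). Negative fitted rates are flagged,
never clipped. The default sampling grids are the experimental schedules
(R₁: 40–992 ms, ten points; R₁ρ: 30–210 ms, six points).

R₁ρ → R₂ uses R₂ = R₁ρ + (R₁ρ − R₁)tan²θ, θ = tan⁻¹(Δν/ν₁) with
ν₁ = 1433 Hz by default; the convention makes Δν = 0 give θ = 0 and
R₂ = R₁ρ, and the transform exactly inverts the rotating-frame average
R₁ρ = R₁sin²θ + R₂cos²θ (property-tested over 10⁴ random inputs).
Offset/spin-lock ratios above 3 trigger a warning.

Rate errors are Monte-Carlo: 100 refits (default) of Gaussian-perturbed
decays at the spectral noise sd, seeded explicitly. τ_c = √(6R₂/R₁ − 7)/
(4πν_N), with ν_N derived from the proton frequency via |γ_N/γ_H| =
0.10137; a negative radicand (R₂/R₁ < 7/6) returns no τ_c with a
"fast-limit" flag. This estimator assumes a single effective reorientation
time per residue; exchange broadening is not corrected for, so slow-µs–ms
dynamics would inflate τ_c. Both chain-average conventions (mean of
per-residue τ_c, and τ_c of chain-mean rates) are reported because they
differ by ~1% and either is defensible; neither is privileged.

## Titration quenching

Ratios are raw bound/free peak heights; no cross-sample normalisation by
default (an optional normalisation by the mean ratio of a declared
unaffected region is provided for when sample concentrations differ).
Segment calling: maximal runs of ok-residues with ratio ≤ threshold
(default 0.5), at least min_length = 3 qualifying residues, with exactly
one flagged (overlapped/proline/missing) residue bridgeable inside a run —
two consecutive flagged residues, or any ok residue above threshold, break
it. The linear-scan caller is property-tested against brute-force interval
enumeration.

## Binding fits

Kinetic SPR: global least squares of the 1:1 Langmuir model over all
concentrations in log-parameter space (log k_a, log k_d, log R_max; bounds
10⁻⁶–10¹², 10⁻¹²–10⁶, 10⁻⁶–10¹² in their units, which only prevent
runaway on degenerate data). Initialisation is deterministic: k_d from
log-linear regression on the dissociation tails, per-curve k_obs from
single-exponential association pre-fits, k_a from the slope of k_obs
vs C. R_max is shared across curves by default (one surface per series);
all points are weighted equally. Mass transport, drift and bulk
refractive-index steps are not modelled; the residual sd is reported so
users can judge. Non-identifiable designs (all C ≫ K_D or ≪ K_D, or no
dissociation decay) attach warnings rather than raising.

Steady state: Req is the mean response over the final plateau window
(default 20 s) of the association phase; curves varying more than 5%
inside the window are excluded with a warning; Req(C) = R_max·C/(C+K_D).

Equilibrium isotherms: the depletion-exact quadratic bound fraction at
fixed labeled concentration L₀ (default 10 nM) over a 16-point 2-fold
dilution (default top 42.5 µM), fitted for (log K_D, S_free, S_bound).
The fitted amplitude over the residual sd is reported as signal-to-noise;
amplitude below 3 residual sd flags the fit low-confidence. Because K_D
is fitted on a log scale and its sampling distribution is right-skewed,
multi-seed recoveries in the tests pool estimates geometrically.

## Transport and imaging

Segmentation: per-interval velocities are centred moving averages of the
frame displacements (default window 3), classified against v_min
(default 0.1 µm/s, states +/−/pause), merged into runs; pauses shorter
than min_pause_frames (default 2) are absorbed into their flanking moving
states. The smoothing blurs each state boundary by up to the half-width,
so by default boundaries are then snapped to where the raw unsmoothed
velocity crosses v_min within that half-width; on clean data this makes
recovered segments exactly the true state runs while keeping the
smoothing's noise robustness. Segment statistics (duration, run length,
signed velocity) always come from the raw positions. These thresholds are
explicit, documented defaults — kymograph packages differ here, and all
are configurable; the tests tie them only to synthetic-truth recovery.

Particle direction is the sign of the net start-to-end displacement, with
|net| < d_min = 0.3 µm called stationary. Spatial statistics normalise
positions to percent of axon length and report density per 100 µm. ROI
quantification dilates the inner mask by 2 px (scipy binary dilation),
estimates the per-pixel background from the surrounding ring and subtracts
it scaled to the inner area. The spindle tilt angle is the folded axis
angle (0–90°) between the centrosome–centrosome vector and the
anterior–posterior axis. The exact 2×2 test enumerates the hypergeometric
distribution with fixed margins; the two-sided p sums point probabilities
≤ the observed one with a 10⁻⁷ relative slack absorbing floating-point
ties, and is cross-checked exhaustively against from-scratch enumeration
for all tables with total ≤ 40 and against an independent implementation.

## Synthetic generators — what they emulate, and what they do not

All generators draw from a seeded NumPy generator and are bit-reproducible.
They emulate: population-weighted helix/coil shifts with Gaussian noise;
monoexponential decays on the experimental time grids; noiseless-kinetics
Langmuir sensorgrams over the experimental ladder (50, 11, 4.5, 1.8,
0.3 µM; 120 s association, 600 s dissociation) plus Gaussian noise;
depletion-exact isotherms (S/N ≈ 20 at the default noise, matching the
instrument-typical value); first-order Markov run-and-pause tracks
(defaults: 0.2 s frames, 60 s tracks, +1.2/−1.5 µm/s, dwell ≈ 3–4 s);
Gaussian puncta on constant background. They do not emulate peak overlap,
baseline drift, mass-transport kinetics, photobleaching, tracking noise
(unless a position-noise sd is set) or non-Markov motor behaviour — so
passing recovery tests demonstrates correctness of the estimators under
their assumed models, not robustness to every real-data artefact.

## Numerical choices and degenerate inputs

Duplicate (residue, nucleus) assignments, glycine CB entries and
bound-only residues are hard errors (auditability over convenience).
Results written as TSV use full repr precision and round-trip to ≥ 12
significant digits. Decay fits on fewer than 3 points, empty ROI masks,
dilations clipped to nothing, zero-length axes and nonpositive physical
parameters raise immediately with the offending residue/value named.
Fisher tables with a zero margin return p = 1 (only one table possible).

## Known limitations

Per-residue SSP parity with any specific published profile is out of
scope (the external program's window/weights are not specified); Hα-based
scoring is not implemented. No model-free order-parameter analysis, no
relaxation-dispersion. SPR fits assume a clean 1:1 interaction — bivalent
or conformational-change schemes are not available. Real kymograph
extraction (detection/linking from movies) is upstream of this package:
tracks are inputs.
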