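# idrkit

Quantitative analysis of transient helices in intrinsically disordered
protein tails — built around the combined NMR / binding / live-imaging
characterisation of a dynein light-intermediate-chain C-terminal tail and
its cargo-adaptor interactions, with seeded synthetic-data generators so
every analysis stage can be exercised and validated without raw
experimental data.

## Who it is for

Structural biologists and cell biologists who need the quantitative layer
of such a study as reusable, tested code: scoring residual structure from
chemical shifts, extracting backbone dynamics from ¹⁵N relaxation, mapping
an adaptor-binding site from titration quenching, fitting 1:1 binding
models to SPR and thermophoresis data, converting CD signals, and reducing
particle-tracking and embryo-imaging measurements to summary statistics.

## What it computes

**Secondary structure propensity (SSP).** For each residue, the observed
secondary shift Δδ = δ_obs − δ_rc of the backbone nuclei (¹Hᴺ, ¹⁵N, ¹³CO,
¹³CA, ¹³CB) is normalised by the full-helix (Δδ_α) or full-sheet (Δδ_β)
reference secondary shift and averaged over a sliding window with weights
∝ |Δδ_ref|². The score is +1 for a fully formed α helix, −1 for a fully
formed β sheet and 0 for coil; it is linear in helical population, so a
segment sampling helix 20% of the time scores ≈ +0.2. CA/CB shifts can be
re-referenced by a 10%-trimmed-mean chain offset.

**¹⁵N relaxation.** Monoexponential fits I(t) = I₀e^(−Rt) give R₁ and
R₁ρ; the transverse rate follows from the spin-lock tilt correction
R₂ = R₁ρ + (R₁ρ − R₁)·tan²θ with θ = tan⁻¹(2πΔν/γ_N B₁). Rate errors come
from Monte-Carlo refits (100 runs, Gaussian spectral noise). The effective
rotational correlation time is τ_c = √(6R₂/R₁ − 7)/(4πν_N). The
heteronuclear NOE is I_sat/I_ref with propagated uncertainty.

**Binding.** The 1:1 Langmuir sensorgram model
R(t) = Req(1 − e^(−k_obs t)), k_obs = k_a C + k_d, Req = C·R_max/(C + K_D)
is fitted globally over a concentration series (kinetic mode) or through
its plateaus (steady state); K_D = k_d/k_a. Equilibrium isotherms use the
depletion-exact bound fraction
FB = ((L₀+T₀+K_D) − √((L₀+T₀+K_D)² − 4L₀T₀))/(2L₀).

**CD.** Molar ellipticity [θ] = m°·M/(10·L·C) in deg·cm²·dmol⁻¹.

**In-vivo quantification.** Particle tracks are decomposed into
anterograde / retrograde / pause segments framed by pauses and reversals;
summaries report particle direction fractions, state time fractions,
segment velocity and run-length distributions and pause statistics. Also:
axon-length-normalised spatial distributions and densities, ROI
intensities with local background subtraction
(final = I_in − (I_out − I_in)/(A_out − A_in)·A_in), spindle tilt angles
from centrosome and embryo-pole coordinates, and an exact two-sided 2×2
test (minimum-likelihood rule).

## Worked example

```bash
python examples/relaxation_rates.py
```

prints (numbers from the seeded simulation in the script):

```
helix-region mean R2 : 6.51 s^-1
coil-region  mean R2 : 3.81 s^-1
chain-average tau_c  : 4.52 ns
tau_c from chain-average rates R1=1.2, R2=4.7 at 700 MHz: 4.56 ns
```

Transiently helical residues relax faster (larger R₂, longer τ_c) than the
flexible linker, and a chain-average τ_c of a few nanoseconds is far below
what a folded domain of this size would show — the quantitative signature
of a disordered tail with embedded transient structure. The other scripts
in `examples/` exercise SSP profiling, titration mapping, binding fits, CD
conversion and transport statistics the same way; each prints its numbers
with a line on what they mean.

A CLI mirrors the library (`idr ssp`, `idr relax`, `idr titrate`,
`idr spr`, `idr mst`, `idr cd`, `idr transport`, `idr spatial`, `idr roi`,
`idr tilt`, `idr fisher`, `idr simulate`); every run writes a manifest
(parameters, seed, version) beside its outputs.

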