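"""15N relaxation: fit decays, correct R1rho to R2, extract tumbling times.

Simulates R1/R1rho decays for a 30-residue chain whose residues 10-20 are
stiffened by a transient helix, then runs the full relaxation pipeline.
"""

import numpy as np

from idrkit.relaxation import (
    R1RHO_TIME_GRID,
    SpectrometerContext,
    SpinLockParams,
    analyze_relaxation,
    r1rho_from_r2,
    tumbling_time,
)
from idrkit.synthetic import gen_decay_series

residues = range(1, 31)
helix = set(range(10, 21))
r1 = {r: 1.3 if r in helix else 1.15 for r in residues}
r2 = {r: 6.5 if r in helix else 3.8 for r in residues}
spinlock = SpinLockParams(spin_lock_hz=1433.0, offset_hz=300.0)
r1rho = {r: r1rho_from_r2(r1[r], r2[r], spinlock) for r in residues}

r1_series, _ = gen_decay_series(r1, noise_sd=0.3, seed=11)
rho_series, _ = gen_decay_series(r1rho, time_grid=R1RHO_TIME_GRID, noise_sd=0.3, seed=12)
result = analyze_relaxation(r1_series, rho_series, SpectrometerContext(700.0),
                            offsets_hz={r: 300.0 for r in residues}, seed=1)

recs = {r.residue: r for r in result.records}
print(f"helix-region mean R2 : {np.mean([recs[r].r2 for r in helix]):.2f} s^-1")
print(f"coil-region  mean R2 : {np.mean([recs[r].r2 for r in residues if r not in helix]):.2f} s^-1")
print(f"chain-average tau_c  : {result.mean_tau_c * 1e9:.2f} ns")
tau, _ = tumbling_time(1.2, 4.7, SpectrometerContext(700.0))
print(f"tau_c from chain-average rates R1=1.2, R2=4.7 at 700 MHz: {tau * 1e9:.2f} ns")
print("Elevated R2 (hence tau_c) marks residues rigidified by transient structure;")
print("a few-ns tau_c is far below a folded ~15 kDa domain, i.e. the chain is disordered.")
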