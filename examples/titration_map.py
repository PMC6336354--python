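"""Titration quenching: locate the binding helix from per-residue ratios.

Constructs a bound/free peak-height profile in which residues 444-454 are
strongly quenched (with one overlapped residue inside the span) and calls
the binding segment.
"""

from idrkit.titration import ResidueStatus, call_binding_segments, quench_profile

free = {r: 100.0 for r in range(430, 471)}
bound = {r: (20.0 if 444 <= r <= 454 else 90.0) for r in free}
statuses = {448: ResidueStatus.OVERLAPPED}
for r in statuses:
    free.pop(r), bound.pop(r)

profile = quench_profile(free, bound, statuses)
for seg in call_binding_segments(profile, threshold=0.5, min_length=3):
    print(f"binding segment: residues {seg.start_residue}-{seg.end_residue}, "
          f"mean bound/free ratio {seg.mean_ratio:.2f}")
print("Ratios near 0.2 mean peaks lose ~80% height on adaptor binding —")
print("the contiguous quenched run marks the helix that docks onto the adaptor.")
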