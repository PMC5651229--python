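"""Analyze one SHIMP impulse and walk through the measured quantities.

Builds a single synthetic head impulse (200 deg/s, ~100 ms wide) with a
VOR slow-phase response (gain 0.9) and an anticompensatory saccade injected
160 ms after the head apex, then runs the per-impulse analysis.
"""

from shimpkit import SimulationSpec, analyze_impulse, simulate_impulse

spec = SimulationSpec(noise_sd=5.0, saccade_latency_ms=160.0, seed=7)
record, truth = simulate_impulse(spec)
a = analyze_impulse(record)

print(f"head peak   : sample {a.head_peak.index}, "
      f"{a.head_peak.velocity:.1f} deg/s, "
      f"prominence {a.head_peak.prominence:.1f} deg/s, "
      f"half-prominence width {a.head_peak.width:.2f} samples")
print(f"VOR peak    : sample {a.vor_peak.index}, "
      f"prominence {a.vor_peak.prominence:.1f} deg/s")
s = a.saccade
print(f"saccade     : sample {s.peak.index} "
      f"(truth {truth.true_saccade_apex}), "
      f"velocity {s.velocity:.1f} deg/s, width {s.width_ms:.1f} ms")
print(f"latency     : {s.latency_ms:.1f} ms after the head peak "
      f"(truth {truth.true_latency_ms:.1f} ms)")
print(f"ESTP bound  : {s.estp_samples:.2f} samples -> "
      f"early saccade: {s.early} (truth: {truth.true_early})")
print(f"QC flags    : {sorted(a.qc) or 'none'}")

# The saccade apex (sample ~90) falls inside the head-movement window
# bounded by ESTP = head apex + 1.5*head width + saccade width, so this
# saccade is classified as early: it began while the head was still moving.
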