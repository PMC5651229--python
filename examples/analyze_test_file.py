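"""Full file-based workflow: simulate a test, write it to CSV, read it back,
analyze every impulse, and print the per-test summary.

The same CSV (or the XML equivalent) is what a recording session would be
exported to; the results JSON mirrors the output panel of the interactive
analysis tool.
"""

import tempfile
from pathlib import Path

from shimpkit import (
    SimulationSpec,
    TestFile,
    analyze_impulse,
    read_csv_test,
    simulate_test,
    summarize_test,
    write_csv_test,
    write_results_json,
)

workdir = Path(tempfile.mkdtemp())
pairs = simulate_test("predictable", 20, base_spec=SimulationSpec(noise_sd=5.0),
                      seed=42)
test = TestFile(
    impulses=tuple(rec for rec, _ in pairs),
    test_id="demo", protocol="predictable", device="synthetic",
)
csv_path = workdir / "demo.csv"
write_csv_test(test, csv_path)

loaded = read_csv_test(csv_path)
analyses = [analyze_impulse(rec) for rec in loaded.impulses]
summary = summarize_test(analyses, loaded.rate_hz)
write_results_json(summary, analyses, workdir / "demo.results.json",
                   metadata={"test_id": "demo", "protocol": "predictable"})

print(f"impulses                : {summary.n_impulses}")
print(f"mean head peak velocity : {summary.mean_head_peak_velocity:.1f} deg/s")
print(f"impulses under 130 deg/s: {summary.n_head_below_130}")
print(f"first-saccade latency   : {summary.first_saccade_latency_mean_ms:.1f}"
      f" +/- {summary.first_saccade_latency_sd_ms:.1f} ms")
print(f"early saccades          : {summary.early.n}/"
      f"{summary.early.n + summary.not_early.n} ({summary.pct_early:.1f}%)")
print(f"early latency           : {summary.early.latency_mean_ms:.1f} ms")
print(f"results JSON written to : {workdir / 'demo.results.json'}")

# Under the highly predictable protocol most saccades start during the head
# movement (short latency, high early percentage); compare with
# protocol_latency_contrast.py for the unpredictable case.
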