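"""Predictability shortens saccade latency: simulate one test per protocol
preset and compare the detected first-saccade latencies descriptively.

Each preset carries the first-saccade latency distribution observed under a
different level of head-impulse predictability. The more predictable the
impulse timing/direction, the earlier the anticompensatory saccade.
"""

from shimpkit import (
    SimulationSpec,
    analyze_impulse,
    compare_protocol_means,
    simulate_test,
    summarize_test,
)

summaries = {}
for seed, name in enumerate(("predictable", "less_predictable", "unpredictable")):
    pairs = simulate_test(name, 200, base_spec=SimulationSpec(noise_sd=5.0),
                          seed=100 + seed)
    analyses = [analyze_impulse(rec) for rec, _ in pairs]
    summaries[name] = [summarize_test(analyses)]

comp = compare_protocol_means(summaries)
print("detected mean first-saccade latency per protocol:")
for name in comp.protocols:
    print(f"  {name:<18} {comp.means_ms[name]:7.2f} ms")
print("pairwise differences:")
for (a, b), d in comp.differences_ms.items():
    print(f"  {a} - {b}: {d:+.2f} ms")

# The unpredictable-minus-predictable difference lands near +65 ms: with no
# way to anticipate the impulse, the refixation saccade waits for actual
# vestibular input instead of being pre-programmed.
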