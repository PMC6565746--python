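"""Call ploidy fractions from a synthetic DNA-content cytometry run.

Simulates 22,000 events at the mixed diploid/tetraploid composition typical
of freshly isolated c-kit+ cardiac interstitial cells (54.5 / 41.8 / 3.7 %),
with 5 % doublets and a little sub-G1 debris, then gates singlets and
anchors the DNA scale on the dominant diploid peak.
"""

from ploidykit.flow import analyze_events
from ploidykit.synth import FlowSimParams, simulate_flow_events

params = FlowSimParams(
    n_events=22_000,
    fractions=(0.5451, 0.418, 0.0369),
    cv=0.05,
    doublet_rate=0.05,
    seed=1,
)
events = simulate_flow_events(params)
gated, result = analyze_events(events, anchor="2n")

print(gated["gate"].value_counts().to_string())
print(f"\ndiploid peak position: {result.reference_2n:,.1f} (channel units)")
for cls in ("2n", "4n", ">4n"):
    print(f"  {cls:>3}: {100 * result.fractions[cls]:5.2f} %  "
          f"(truth {100 * dict(zip(('2n','4n','>4n'), params.fractions))[cls]:.2f} %)")
print("\nrecovered fractions should sit within ~1 point of truth: doublets")
print("(which mimic tetraploid DNA content) are removed by width-vs-area gating.")
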