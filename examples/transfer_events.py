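"""Detect conjugative transfer events in a donor/recipient co-culture.

Simulates a derepressed (dmfsR) donor strain mixed 1:2 with ICE-free
recipients, then scans for recipients that acquire a LacI-CFP focus next to
a tc donor and later (3.5-10 h) switch on the eCherry integration reporter.
"""
from collections import Counter

from icetrack import PipelineConfig, run_pipeline
from icetrack.transfer import donor_distribution_vs_background

bundle = run_pipeline(PipelineConfig(
    preset="dmfsR", seed=11,
    overrides=dict(initial_cells=300, recipient_fraction=0.66,
                   colony_spacing=2.5, frames=80)))

events = bundle["transfer_events"]
print("event outcomes:", dict(Counter(e.status for e in events)))
print("unassigned recipient foci (no adjacent tc donor):",
      len(bundle["transfer_unassigned"]))

donors, background = donor_distribution_vs_background(
    events, bundle["distributions"]["tc"])
print(f"transferring donors with >=3 foci: "
      f"{100 * donors.proportion_at_least(3):.0f} %  "
      f"(all tc cells: {100 * background.proportion_at_least(3):.0f} %)")
# Transfer probability grows with the excised copy number, so successful
# donors are enriched for high focus counts relative to the tc background.
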