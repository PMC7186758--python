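"""Spike-rate analyses over the detected event catalog.

Reads the fixture and the event catalog, bins spikes into 100 ms bins on
the behavioral clock and writes, under results/analysis/:

* angular_profiles.csv — mean rate per 10 deg bin of gravity-relative and
  relative-body-axis angle, whole recording and per quarter, with Rayleigh
  uniformity tests in summary.json;
* decile_distance.csv / distance_split.csv — nearest-bee distance across
  spike-rate deciles and the 5 cm near/far split per quarter;
* peth.csv — perievent time histograms (+/-8 s) for walking onset and the
  two contact states, with pre-event peak latencies;
* variance_samples.csv / variance_comparisons.csv — per-window spike-rate
  variance by state and the alpha/6 Bonferroni pairwise rank-sum table.
"""

import json
from pathlib import Path

from socialspike.config import AnalysisConfig
from socialspike.pipeline import cmd_analyze

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    summary = cmd_analyze(
        ROOT / "fixture" / "tracks.csv",
        ROOT / "fixture" / "spikes.txt",
        ROOT / "detect" / "events.csv",
        AnalysisConfig(),
        ROOT / "analysis",
    )
    print(json.dumps(summary, indent=1, sort_keys=True))
    peth = summary.get("peth", {})
    ac = peth.get("active_contact")
    if isinstance(ac, dict) and ac.get("peak_latency_s"):
        print(f"\nphasic pre-contact lead (active contact): {ac['peak_latency_s']:.2f} s "
              f"over {ac['n_events']} events")
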