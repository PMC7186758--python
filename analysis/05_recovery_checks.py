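"""Parameter-recovery summary: compare what the pipeline measured on the
synthetic session against the planted ground truth.

Reads results/fixture/truth.json and results/analysis/summary.json and
prints, side by side: planted vs detected event counts, the planted phasic
lead vs the PETH peak latency, and the planted variance-sigma ordering vs
the significant pairwise comparisons.  This is the only script that opens
the truth file.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    truth = json.loads((ROOT / "fixture" / "truth.json").read_text())
    summary = json.loads((ROOT / "analysis" / "summary.json").read_text())
    events = pd.DataFrame(truth["events"])
    catalog = pd.read_csv(ROOT / "detect" / "events.csv")

    print("event counts (planted -> detected):")
    for state in ("alone", "walking_onset", "passive_contact", "active_contact"):
        n_t = int((events["state"] == state).sum())
        n_d = int((catalog["state"] == state).sum())
        print(f"  {state:16s} {n_t:4d} -> {n_d:4d}")
    print("  (free focal locomotion adds genuine walking onsets beyond the planted ones)")

    lead = truth["params"]["lead_s"]
    beta = truth["params"]["beta_dist_hz"]
    ac = summary["peth"].get("active_contact")
    if isinstance(ac, dict):
        print(f"\nphasic lead: planted {lead:.2f} s, PETH peak at "
              f"{ac['peak_latency_s']:.2f} s before contact ({ac['n_events']} active contacts)")
        if beta > 0:
            print(f"  note: with the distance effect on (beta = {beta:g} Hz) the "
                  "approach ramp peaks at the contact moment and superimposes on "
                  "the planted bump, pulling the PETH peak toward 0 lag; the "
                  "isolated-bump recovery (tests, scripts/acceptance.py) recovers "
                  "the planted lead to within one bin")

    comp_path = ROOT / "analysis" / "variance_comparisons.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path)
        sig = comp[comp["significant"] == True]  # noqa: E712
        print(f"\nplanted sigma_state: {truth['params']['sigma_state']}")
        print("significant variance pairs at alpha/6:")
        print(sig[["state_a", "state_b", "p", "stars"]].to_string(index=False)
              if len(sig) else "  none")
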