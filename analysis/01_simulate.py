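"""Generate the study's synthetic recording: a 600 s colony session with
planted social episodes and a behavior-coupled spike train.

Writes results/fixture/{tracks.csv, spikes.txt, truth.json}.  The truth
file is for later recovery checks only; no downstream script reads it
during detection or analysis.
"""

from pathlib import Path

from socialspike.pipeline import cmd_simulate
from socialspike.synthetic import SimConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "fixture"

if __name__ == "__main__":
    cfg = SimConfig(duration_s=600.0, seed=0, n_onset_events=4)
    paths = cmd_simulate(cfg, OUT)
    print(f"simulated {cfg.duration_s:.0f} s of colony at {cfg.frame_rate_hz:.0f} fps "
          f"({1 + cfg.n_other_bees} bees, seed {cfg.seed})")
    for k, p in paths.items():
        print(f"  {k}: {p}")
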