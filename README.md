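# socialspike

Analysis pipeline for relating the spike activity of a single mushroom-body
extrinsic neuron (MB EN), recorded extracellularly in a honeybee moving
freely inside a 55 × 55 cm observation hive, to the bee's self-initiated
social behavior.  The pipeline takes multi-animal tracking tables (bee id,
centroid x/y in cm, long-body-axis angle, 10 frames/s) and the sorted spike
times of the one recorded unit, and produces:

* **social-state windows** — 4 s windows labeled *alone*, *random*,
  *walking onset*, *passive contact* or *active contact* from distance and
  movement rules (10 cm alone radius, 1 cm contact radius, < 1 mm / 2 s
  stillness, sync at the 2 s mark);
* **perievent time histograms** (±8 s, 100 ms bins, per-event normalized
  relative rates) with the pre-event peak latency — the *phasic lead* of a
  rate increase anticipating an active contact;
* **spike-rate variance per window** (population variance of the 40 in-window
  100 ms rates) compared across states with rank-sum tests at
  Bonferroni-corrected α/6 star thresholds (0.0083 / 0.0017 / 0.00083);
* **distance and orientation profiles** — nearest-bee distance across
  spike-rate deciles (top vs. bottom decile rank-sum), a 5 cm near/far
  split per data quarter, and 10° angular rate profiles with weighted
  Rayleigh uniformity tests.

A synthetic colony generator (`socialspike.synthetic`) plants all of these
effects with known parameters — scripted approach episodes, a
distance-dependent rate kernel β·e^(−d/d₀), a pre-contact raised-cosine
bump centered *lead* seconds before contact, and state-dependent log-normal
rate multipliers — so every stage is validated by parameter recovery.
Model details and design decisions are in [docs/methods.md](docs/methods.md).

## Worked example

```python
from socialspike import SimConfig, AnalysisConfig
from socialspike.pipeline import run_all

summary = run_all(SimConfig(duration_s=600, seed=0, n_onset_events=4),
                  AnalysisConfig(), seed=0, out_dir="results_demo")
print(summary["peth"]["active_contact"])
print(summary["decile_top_vs_bottom"])
```

prints (seed 0):

```
{'n_events': 12, 'n_dropped_context': 0, 'peak_latency_s': 0.15000000000000002}
{'statistic': -14.780600413528315, 'p': 1.9541635313657146e-49}
```

Twelve active contacts were detected (all of them planted), and the
distance distribution of the top spike-rate decile differs from the bottom
decile at p ≈ 10⁻⁴⁹ — the planted "high rate when close" coupling,
recovered.  The PETH peak sits 0.15 s before contact here because the
distance-ramp effect (rate rising as the partner closes in) is
superimposed on the planted 1.2 s phasic bump; with the distance effect
switched off the planted lead is recovered to within one 100 ms bin (see
`analysis/05_recovery_checks.py` and the tests).

The same stages run from the shell:

```
socialspike run-all --seed 0 --out results_demo --figures
```

or as the numbered narrative under `analysis/` (`01_simulate.py` …
`05_recovery_checks.py`), which writes its tables under `results/`.

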