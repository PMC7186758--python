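"""Collect the analysis tables into report.json and render figures
(PETH overlay, variance-by-state boxplot) under results/analysis/figures/.
"""

from pathlib import Path

from socialspike.pipeline import cmd_report

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    path = cmd_report(ROOT / "analysis", figures=True)
    print(f"report: {path}")
    figdir = ROOT / "analysis" / "figures"
    for p in sorted(figdir.glob("*.png")):
        print(f"  figure: {p}")
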