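"""Secondary analyses: linear scans of the log glycaemic markers (fasting
glucose, fasting insulin, HOMA-IR, 2 h OGTT glucose) on the morning-exam
biomarker subsample, with its additional exclusions (missing outcome,
diabetes medication, OGTT protocol eligibility).

Writes one result directory per marker under results/markers/.
"""

import json
from pathlib import Path

import pandas as pd

from actiscan.pipeline import RunConfig, run
from actiscan.plotting import plot_curves

DATA = Path("scratch/data")
OUT = Path("results/markers")


def main():
    for analysis in ("fasting_glucose", "fasting_insulin", "homa_ir", "ogtt"):
        out = run(
            RunConfig(
                minutes_path=str(DATA / "minutes.csv"),
                participants_path=str(DATA / "participants.csv"),
                analysis=analysis,
                framings=("relative",),
                variance="taylor",
                out_dir=str(OUT / analysis),
                seed=0,
            )
        )
        manifest = json.loads((out / "manifest.json").read_text())
        counts = manifest["counts"]
        curve = pd.read_csv(out / "curve_relative.tsv", sep="\t")
        plot_curves(curve, out / "fig_q5_vs_q1.png", logistic=False, title=f"{analysis}, Q5 vs Q1 (relative)")
        n_ok = int((curve["status"] == "ok").sum())
        print(f"{analysis}: n={counts['included']} after cascade; {n_ok}/24 windows estimable")


if __name__ == "__main__":
    main()
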