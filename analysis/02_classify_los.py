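#!/usr/bin/env python
"""Classify LOS on the published-composition fixtures and the synthetic cohort.

Applies the sex-specific 97th-percentile weight rule to the D56 and D105
published-summary fixtures (with the published thresholds) and to the
simulated cohort from 01 (with thresholds recomputed from its AI controls).
Writes labels and prevalence summaries under results/phenotyping/.
"""

import json
from pathlib import Path

import pandas as pd

from loscreen import pipeline_io as pio
from loscreen.phenotyping import classify_los, los_prevalence
from loscreen.synthcohort import make_published_fixture

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "phenotyping"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}

    for day in (56, 105):
        records, thresholds = make_published_fixture(day)
        labels = classify_los(records, thresholds=thresholds)
        prevalence = los_prevalence(labels)
        n_ivp = sum(1 for r in records if r.group == "IVP")
        n_los = sum(1 for v in labels.labels.values() if v == "IVP-LOS")
        summary[f"D{day}"] = {
            "thresholds_g": thresholds,
            "n_ivp": n_ivp,
            "n_los": n_los,
            "prevalence_pct": round(100 * prevalence, 2),
        }
        pd.Series(labels.labels, name="label").rename_axis("fetus_id").to_csv(
            OUT / f"labels_D{day}.csv"
        )
        print(f"D{day}: {n_los}/{n_ivp} IVP fetuses LOS ({100 * prevalence:.1f}%) "
              f"at thresholds {thresholds}")

    sim_path = ROOT / "sim" / "morphometry.csv"
    if sim_path.exists():
        records = pio.read_morphometry_csv(sim_path)
        labels = classify_los(records)
        summary["simulated"] = {
            "thresholds_g": {k: round(v, 2) for k, v in labels.thresholds.items()},
            "prevalence_pct": round(100 * los_prevalence(labels), 2),
        }
        pd.Series(labels.labels, name="label").rename_axis("fetus_id").to_csv(
            OUT / "labels_simulated.csv"
        )
        print(f"simulated cohort: prevalence {summary['simulated']['prevalence_pct']}% "
              f"at recomputed thresholds {summary['simulated']['thresholds_g']}")

    (OUT / "summary.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
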