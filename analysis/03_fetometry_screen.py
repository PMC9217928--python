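#!/usr/bin/env python
"""D55 ultrasound product-index screening.

Computes the six-measurement product for every fetus in the D56 and D105
exam fixtures, derives the control-max threshold, flags fetuses above it,
and reports product-vs-weight correlations; repeats on the simulated cohort
from 01 if present.  Writes screening tables under results/fetometry/.
"""

import json
from pathlib import Path

from loscreen import pipeline_io as pio
from loscreen.fetometry import fetometry_report
from loscreen.phenotyping import classify_los
from loscreen.synthcohort import make_fetometry_fixture, make_published_fixture

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "fetometry"


def run_one(name, exams, records, labels):
    table, correlations = fetometry_report(exams, records, labels)
    table.to_csv(OUT / f"screen_{name}.csv", index=False)
    flagged = sorted(table.loc[table["flagged"], "fetus_id"])
    t = float(table["threshold"].iloc[0])
    print(f"{name}: control-max threshold {t:.2f} cm^6, "
          f"{len(flagged)} flagged: {flagged}")
    for c in correlations:
        print(f"  corr {c.pair[0]} vs weight: r = {c.r:.2f} (p = {c.p:.2g}, n = {c.n})")
    return {"threshold": round(t, 2), "flagged": flagged,
            "correlations": {c.pair[0]: round(c.r, 3) for c in correlations}}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}
    for day in (56, 105):
        records, wt = make_published_fixture(day)
        exams, _ = make_fetometry_fixture(day)
        labels = classify_los(records, thresholds=wt)
        summary[f"D{day}"] = run_one(f"D{day}", exams, records, labels)

    sim_morph = ROOT / "sim" / "morphometry.csv"
    sim_us = ROOT / "sim" / "ultrasound.csv"
    if sim_morph.exists() and sim_us.exists():
        records = pio.read_morphometry_csv(sim_morph)
        exams = pio.read_ultrasound_csv(sim_us)
        labels = classify_los(records)
        summary["simulated"] = run_one("simulated", exams, records, labels)

    (OUT / "summary.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
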