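#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes, under results/sim/: a D105 cohort (morphometry + D55 ultrasound
exams), per-dam leukocyte sample metadata for both blood-draw days, a
negative-binomial count matrix with two "extreme" dams carrying a planted
expression signature, a CT table with planted fold differences, and the
ground-truth JSONs needed for parameter-recovery checks.
"""

import sys
from pathlib import Path

from loscreen import pipeline_io as pio
from loscreen.cli import build_leukocyte_samples
from loscreen.phenotyping import classify_los
from loscreen.synthcohort import SimConfig, simulate_cohort, simulate_counts, simulate_qpcr

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main(seed: int = 7) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=seed, day=105)

    records, exams, cohort_truth = simulate_cohort(config)
    labels = classify_los(records)
    samples = build_leukocyte_samples(records, labels)
    counts, counts_truth = simulate_counts(config, samples)
    folds = {s.sample_id: (4.0 if s.extreme else 1.0) for s in samples if s.day == 105}
    ct = simulate_qpcr(config, folds)

    pio.write_morphometry_csv(records, OUT / "morphometry.csv")
    pio.write_ultrasound_csv(exams, OUT / "ultrasound.csv")
    pio.write_samplemeta_csv(samples, OUT / "samplemeta.csv")
    pio.write_counts_tsv(counts, OUT / "counts.tsv")
    pio.write_ct_csv(ct, OUT / "ct.csv")
    pio.write_truth_json(cohort_truth, OUT / "cohort_truth.json")
    pio.write_truth_json(counts_truth, OUT / "counts_truth.json")

    n_ivp = sum(1 for r in records if r.group == "IVP")
    n_overgrown = sum(1 for v in cohort_truth.component.values() if v == "overgrown")
    print(f"cohort: {len(records)} fetuses ({n_ivp} IVP, {n_overgrown} truly overgrown)")
    print(f"leukocyte samples: {len(samples)} ({sum(s.extreme for s in samples)} extreme)")
    print(f"counts: {counts.n_genes} genes x {counts.n_samples} samples -> {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
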