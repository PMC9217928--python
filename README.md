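# loscreen

Screening tools for **large offspring syndrome (LOS)** in bovine pregnancy.

In vitro production (IVP) of cattle embryos can cause congenital fetal
overgrowth (LOS, the counterpart of human Beckwith–Wiedemann syndrome),
which risks dystocia and the loss of dam and calf. No prenatal test for LOS
exists. This package implements, as a tested reusable pipeline, the
analytical chain used to ask whether LOS is identifiable **during**
pregnancy from fetal ultrasonography and maternal blood:

1. **Weight classification** — an IVP fetus is LOS when its collection
   weight satisfies `w ≥ Q₀.₉₇(controls of same sex and day)`, the
   sex-specific 97th percentile (Hyndman–Fan type 7) of artificial
   insemination (AI) control weights.
2. **D55 ultrasound product index** — the product
   `P = AD·AH·CRL·HL·TH·TD` (cm⁶) of six day-55 biometrics; a fetus is
   screen-positive when `P` strictly exceeds the maximum control product
   (biparietal diameter is measured but excluded: it does not track
   collection weight).
3. **Sex-ratio tests** — exact one-sided binomial tail
   `p = Σ_{k≤n_f} C(n,k)/2ⁿ` for a deficiency of females against the 1:1
   expectation.
4. **Maternal-leukocyte count analytics** — median-of-ratios, TMM and
   upper-quartile size factors; UPGMA (average-linkage) clustering of
   samples on euclidean distances; per-gene negative-binomial GLM
   likelihood-ratio tests (`log μ = Xβ + offset`, Cox–Reid dispersion,
   χ² reference) under two backend configurations whose
   Benjamini–Hochberg-significant gene sets are intersected into a
   consensus candidate list; reference-gene selection for qPCR
   (never-differential in both backends and CV ≤ 0.10).
5. **ΔΔCT quantification** — fold difference `2^(−ΔΔCT)` of a target
   normalized to the geometric mean of reference genes and referred to a
   baseline group mean.

Because the study's raw per-animal tables are not published, the package
ships a seeded synthetic-cohort generator (`loscreen.synthcohort`) with the
statistical structure the analysis assumes, plus deterministic
published-summary fixtures that reconstruct cohorts from printed subgroup
sizes, weight ranges and thresholds.

## Worked example

```python
from loscreen.synthcohort import make_published_fixture, make_fetometry_fixture
from loscreen.phenotyping import classify_los, los_prevalence, sex_ratio_test
from loscreen.fetometry import FetometryResult, product_index, control_threshold, screen

records, thresholds = make_published_fixture(105)     # published D105 composition
labels = classify_los(records, thresholds=thresholds)
print(thresholds)                                  # {'M': 548.92, 'F': 463.14}
print(f"{100 * los_prevalence(labels):.1f}%")      # 37.0%  (17 of 46 IVP fetuses)

exams, _ = make_fetometry_fixture(105)
results = [FetometryResult(e.fetus_id, product_index(e)) for e in exams]
t = control_threshold(results, labels)
print(round(t, 2))                                 # 79.92  (max control product, cm^6)
print(sorted(r.fetus_id for r in screen(results, t) if r.flagged))
                                                   # ['604B', '664']  (the two extremes)
print(round(sex_ratio_test(13, 46).p_value, 4))    # 0.0023 (IVP female deficit)
```

The male threshold 548.92 g flags the 8 heaviest IVP males and the female
threshold 463.14 g flags 9 IVP females, a 37% prevalence; only the two most
extreme LOS fetuses (986 g and 1080 g at day 105) exceed the day-55
ultrasound product threshold, i.e. the index catches extreme overgrowth
months before collection but not milder cases. The female deficit in the
IVP arm (13 of 46) is highly unlikely under a 1:1 sex ratio.

The numbered scripts under `analysis/` run the full chain as a narrative —
`01` simulates a cohort with counts and CT tables, `02`–`04` classify and
test it, `05` runs clustering, differential expression and consensus, `06`
quantifies qPCR folds — writing their tables under `results/`.

There is also a CLI: `loscreen simulate|fixture|classify|fetometry|
sexratio|normalize|cluster|de|consensus|refgenes|qpcr|run`.

## Layout

- `src/loscreen/phenotyping.py` — percentile rule, labels, sex-ratio test,
  umbilicus/CRL image calibration
- `src/loscreen/fetometry.py` — product index, control-max threshold,
  screening, correlations
- `src/loscreen/leukotranscript/` — count containers, normalization,
  UPGMA clustering, NB-LRT engine, BH, consensus, reference genes
- `src/loscreen/qpcr.py` — geometric-mean reference normalization, ΔΔCT
- `src/loscreen/synthcohort.py` — generator + published-summary fixtures
- `src/loscreen/pipeline_io.py`, `src/loscreen/cli.py` — table I/O,
  config, orchestration, CLI
- `docs/methods.md` — models, parameters, and design choices
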