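"""Day-55 ultrasound fetometry: the six-measurement product index.

No single D55 ultrasonographic measurement separates overgrown (LOS) fetuses
from controls, but the product of six of them — abdominal diameter (AD),
abdominal height (AH), crown-rump length (CRL), head length (HL), thoracic
height (TH) and thoracic diameter (TD) — correlates strongly with weight at
collection and flags the most extreme overgrowth cases.  Biparietal diameter
(BPD) is measured but excluded from the product: it shows no correlation
with collection weight.

The screening threshold is the maximum product observed among AI controls;
a fetus is flagged only when its product is strictly above the threshold
("on or below" is unflagged).  A fixed threshold (conventionally 100 cm^6)
is supported as an alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phenotyping import LOSLabelSet, FetusRecord, LABEL_CONTROL

#: the six measurements entering the product index (BPD deliberately absent)
PRODUCT_MEASUREMENTS = ("AD", "AH", "CRL", "HL", "TH", "TD")

#: conventional fixed screening line, cm^6
FIXED_THRESHOLD = 100.0


@dataclass
class UltrasoundExam:
    """The seven D55 biometric measurements of one fetus, in cm."""

    fetus_id: str
    AH: float  # abdominal height
    AD: float  # abdominal diameter
    TD: float  # thoracic diameter
    TH: float  # thoracic height
    CRL: float  # crown-rump length
    HL: float  # head length
    BPD: float  # biparietal diameter
    day: int = 55


@dataclass
class FetometryResult:
    fetus_id: str
    product: float  # cm^6
    threshold: float | None = None
    flagged: bool = False


@dataclass
class CorrelationReport:
    pair: tuple[str, str]
    r: float
    p: float
    n: int


def product_index(exam: UltrasoundExam) -> float:
    """P = AD x AH x CRL x HL x TH x TD, in cm^6."""
    product = 1.0
    for name in PRODUCT_MEASUREMENTS:
        value = getattr(exam, name, None)
        if value is None or not math.isfinite(value) or value <= 0:
            raise ValueError(
                f"measurement {name!r} missing or non-positive for fetus {exam.fetus_id}"
            )
        product *= value
    return product


def control_threshold(
    results: list[FetometryResult], labels: LOSLabelSet
) -> float:
    """Screening threshold T = max product over Control-AI fetuses."""
    control_products = [
        r.product for r in results if labels.labels.get(r.fetus_id) == LABEL_CONTROL
    ]
    if not control_products:
        raise ValueError("no Control-AI fetuses with an ultrasound exam")
    return max(control_products)


def screen(
    results: list[FetometryResult], threshold: float
) -> list[FetometryResult]:
    """Flag every fetus whose product is strictly above the threshold.

    Returns new results carrying threshold and flag; the input is unchanged.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return [
        FetometryResult(
            fetus_id=r.fetus_id,
            product=r.product,
            threshold=threshold,
            flagged=r.product > threshold,
        )
        for r in results
    ]


def correlate(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationReport:
    """Pearson correlation with a two-sided p from the t reference distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    res = stats.pearsonr(x, y)
    return CorrelationReport(pair=pair, r=float(res.statistic), p=float(res.pvalue), n=x.size)


def fetometry_report(
    exams: list[UltrasoundExam],
    fetuses: list[FetusRecord],
    labels: LOSLabelSet,
    threshold: float | None = None,
) -> tuple[pd.DataFrame, list[CorrelationReport]]:
    """Join exams, weights and labels into a per-fetus screening table.

    Returns a DataFrame (fetus_id, group label, sex, weight_g, product,
    threshold, flagged) sorted by fetus_id, plus Pearson correlations of the
    product index against collection weight computed overall, per group
    (AI / IVP) and per sex.  If ``threshold`` is None the control-max
    threshold is used.  Ids present on one side of the join but not the
    other are warned about, never silently dropped from the warning.
    """
    by_id = {f.fetus_id: f for f in fetuses}
    exam_ids = {e.fetus_id for e in exams}
    unmatched = sorted(exam_ids.symmetric_difference(by_id))
    if unmatched:
        warnings.warn(f"ids without a full exam/record pair: {unmatched}", stacklevel=2)

    usable = [e for e in exams if e.fetus_id in by_id]
    if not usable:
        warnings.warn("no exams join to fetus records; empty report", stacklevel=2)
        return (
            pd.DataFrame(
                columns=["fetus_id", "label", "sex", "weight_g", "product", "threshold", "flagged"]
            ),
            [],
        )

    results = [FetometryResult(e.fetus_id, product_index(e)) for e in usable]
    if threshold is None:
        threshold = control_threshold(results, labels)
    results = screen(results, threshold)

    rows = []
    for r in sorted(results, key=lambda r: r.fetus_id):
        f = by_id[r.fetus_id]
        rows.append(
            {
                "fetus_id": r.fetus_id,
                "label": labels.labels.get(r.fetus_id, "unlabelled"),
                "sex": f.sex,
                "weight_g": f.weight,
                "product": r.product,
                "threshold": threshold,
                "flagged": r.flagged,
            }
        )
    table = pd.DataFrame(rows)

    correlations = []
    def corr_subset(mask: pd.Series, name: str) -> None:
        sub = table[mask]
        if len(sub) >= 3 and sub["product"].std() > 0 and sub["weight_g"].std() > 0:
            correlations.append(
                correlate(sub["product"], sub["weight_g"], pair=(f"product[{name}]", "weight"))
            )

    corr_subset(pd.Series(True, index=table.index), "all")
    corr_subset(table["label"] == LABEL_CONTROL, "AI")
    corr_subset(table["label"] != LABEL_CONTROL, "IVP")
    for sex in ("M", "F"):
        corr_subset(table["sex"] == sex, sex)
    return table, correlations
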