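"""Large offspring syndrome (LOS) phenotyping.

LOS is a congenital overgrowth condition of ruminant fetuses produced by in
vitro embryo production (IVP).  Following the convention used for
Beckwith-Wiedemann syndrome in humans, an IVP fetus is called LOS when its
weight is at or above the 97th percentile of the weight of artificial
insemination (AI) control fetuses of the same sex and gestation day.

This module implements the percentile threshold, the three-way labelling
(Control-AI / IVP-Normal / IVP-LOS), LOS prevalence, the exact one-sided
binomial test for a deficiency of females against the 1:1 sex ratio, and the
image-calibration umbilicus / crown-rump-length ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

GROUP_AI = "AI"
GROUP_IVP = "IVP"
LABEL_CONTROL = "Control-AI"
LABEL_NORMAL = "IVP-Normal"
LABEL_LOS = "IVP-LOS"

#: side length of the calibration squares in fetal photographs, in cm
CALIBRATION_SQUARE_CM = 2.54


@dataclass
class FetusRecord:
    """One collected fetus.

    ``collection_measurements`` holds the morphometry taken at collection
    (crown-rump length, heart girth, forelimb length, biparietal length,
    abdominal height, head length, thoracic height), in cm.
    """

    fetus_id: str
    dam_id: str
    group: str  # "AI" or "IVP"
    sex: str  # "M" or "F"
    day: int  # gestation day of collection (56 or 105)
    weight: float  # grams
    twin: bool = False
    collection_measurements: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in (GROUP_AI, GROUP_IVP):
            raise ValueError(f"unknown group {self.group!r} for fetus {self.fetus_id}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r} for fetus {self.fetus_id}")
        if not self.weight > 0:
            raise ValueError(f"non-positive weight for fetus {self.fetus_id}")
        for name, value in self.collection_measurements.items():
            if not value > 0:
                raise ValueError(
                    f"non-positive measurement {name!r} for fetus {self.fetus_id}"
                )


@dataclass
class LOSLabelSet:
    """Sex-specific weight thresholds and the resulting per-fetus labels."""

    thresholds: dict[str, float]  # sex -> grams
    labels: dict[str, str]  # fetus_id -> Control-AI / IVP-Normal / IVP-LOS


@dataclass
class SexRatioResult:
    n_female: int
    n_total: int
    p_value: float
    null_prob: float = 0.5


@dataclass
class UmbilicusRatioResult:
    scale: float  # cm per pixel
    umbilicus_cm: float
    crl_cm: float
    ratio: float


def percentile(values, q: float) -> float:
    """Hyndman-Fan type-7 percentile (linear interpolation of order statistics).

    This is the default convention of the major statistical packages:
    ``h = (n - 1) q + 1`` on the sorted values, interpolating linearly
    between the floor(h)-th and ceil(h)-th order statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no control fetuses of this sex")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"percentile level q={q} outside [0, 1]")
    return float(np.quantile(values, q, method="linear"))


def classify_los(
    fetuses: list[FetusRecord],
    q: float = 0.97,
    thresholds: dict[str, float] | None = None,
) -> LOSLabelSet:
    """Label every fetus Control-AI, IVP-Normal or IVP-LOS.

    The threshold for each sex is the ``q``-th percentile of the AI control
    weights of that sex (type 7), unless explicit ``thresholds`` are given
    (e.g. published values).  An IVP fetus is LOS iff its weight is >= the
    threshold for its sex (inclusive).  AI fetuses are never LOS.  All
    fetuses must come from a single collection day: thresholds are defined
    per day and days are never pooled.
    """
    if not fetuses:
        raise ValueError("no fetuses to classify")
    days = {f.day for f in fetuses}
    if len(days) > 1:
        raise ValueError(f"mixed collection days {sorted(days)}; classify one day at a time")

    sexes_needed = sorted({f.sex for f in fetuses})
    if thresholds is None:
        thresholds = {}
        for sex in sexes_needed:
            controls = [f.weight for f in fetuses if f.group == GROUP_AI and f.sex == sex]
            if not controls:
                raise ValueError(f"no AI control fetuses of sex {sex!r}")
            thresholds[sex] = percentile(controls, q)
    else:
        missing = [s for s in sexes_needed if s not in thresholds]
        if missing:
            raise ValueError(f"no threshold provided for sex {missing[0]!r}")
    if any(t <= 0 for t in thresholds.values()):
        raise ValueError("thresholds must be strictly positive")

    labels = {}
    for f in fetuses:
        if f.group == GROUP_AI:
            labels[f.fetus_id] = LABEL_CONTROL
        elif f.weight >= thresholds[f.sex]:
            labels[f.fetus_id] = LABEL_LOS
        else:
            labels[f.fetus_id] = LABEL_NORMAL
    return LOSLabelSet(thresholds=dict(thresholds), labels=labels)


def los_prevalence(labels: LOSLabelSet) -> float:
    """Fraction of IVP fetuses labelled LOS."""
    n_ivp = sum(1 for v in labels.labels.values() if v in (LABEL_NORMAL, LABEL_LOS))
    if n_ivp == 0:
        raise ValueError("no IVP fetuses among the labels")
    n_los = sum(1 for v in labels.labels.values() if v == LABEL_LOS)
    return n_los / n_ivp


def sex_ratio_test(n_female: int, n_total: int) -> SexRatioResult:
    """Exact one-sided binomial test for a deficiency of females vs 1:1.

    p = P(X <= n_female) for X ~ Binomial(n_total, 1/2), computed exactly.
    """
    if n_female > n_total:
        raise ValueError(f"n_female={n_female} exceeds n_total={n_total}")
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    p = stats.binomtest(n_female, n_total, p=0.5, alternative="less").pvalue
    return SexRatioResult(n_female=n_female, n_total=n_total, p_value=float(p))


def umbilicus_ratio(
    square_side_px: float, umbilicus_px: float, crl_px: float
) -> UmbilicusRatioResult:
    """Umbilicus-diameter / crown-rump-length ratio from a calibrated photo.

    The collection surface carries squares of known side (2.54 cm); pixel
    lengths traced on the image are converted to cm through that scale.  The
    calibration cancels in the ratio, but both absolute lengths are reported.
    """
    for name, v in (
        ("square_side_px", square_side_px),
        ("umbilicus_px", umbilicus_px),
        ("crl_px", crl_px),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    scale = CALIBRATION_SQUARE_CM / square_side_px
    umb_cm = umbilicus_px * scale
    crl_cm = crl_px * scale
    return UmbilicusRatioResult(
        scale=scale, umbilicus_cm=umb_cm, crl_cm=crl_cm, ratio=umb_cm / crl_cm
    )
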