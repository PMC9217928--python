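"""Synthetic cohorts, count matrices and CT tables for the LOS screen.

The study's raw per-animal tables are not published, so the pipeline is
exercised on two kinds of stand-ins:

* a seeded stochastic generator (`simulate_cohort`, `simulate_counts`,
  `simulate_qpcr`) producing data with the statistical structure the
  analysis assumes — AI singletons vs two-embryo IVP transfers, sex-specific
  lognormal weights with a two-component overgrowth mixture, allometric
  ultrasound biometry with the overgrowth effect attenuated at D55,
  negative-binomial counts with dam-specific effects and a planted
  "extreme dam" expression signature, and CT tables generated from known
  fold differences;
* deterministic "published-summary" fixtures (`make_published_fixture`,
  `make_fetometry_fixture`) that reconstruct cohorts from printed subgroup
  sizes, weight ranges and thresholds, interpolating weights evenly within
  each printed range.  These are transparently synthetic: they reproduce
  the published classification counts, not the unpublished raw data.

All randomness flows from a single seed through named substreams, so
e.g. enlarging the gene panel does not perturb the cohort stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .phenotyping import FetusRecord, GROUP_AI, GROUP_IVP
from .fetometry import UltrasoundExam, PRODUCT_MEASUREMENTS
from .leukotranscript.containers import CountMatrix, SampleMeta

# substream indices off the master seed
_STREAM_COHORT, _STREAM_COUNTS, _STREAM_QPCR = 0, 1, 2

#: lognormal weight parameters (meanlog, sdlog) per (sex, day), in grams,
#: matched to the printed AI control means and SDs
DEFAULT_WEIGHT_PARAMS = {
    ("M", 56): (2.1611, 0.1507),
    ("F", 56): (2.1229, 0.1855),
    ("M", 105): (6.1992, 0.0890),
    ("F", 105): (6.0282, 0.0864),
}

#: D55 ultrasound base values (cm) for a reference-weight fetus
ULTRASOUND_BASE = {
    "AH": 1.90, "AD": 1.80, "TD": 1.75, "TH": 1.70,
    "CRL": 4.90, "HL": 2.00, "BPD": 1.50,
}

#: collection morphometry base values (cm) for a reference-weight D105 fetus
COLLECTION_BASE_D105 = {
    "crown_rump_length": 30.0, "heart_girth": 18.0, "forelimb_length": 9.0,
    "biparietal_length": 4.0, "abdominal_height": 7.0, "head_length": 8.0,
    "thoracic_height": 6.0,
}


@dataclass
class SimConfig:
    """Parameters of the cohort / count / CT generators.

    Defaults reflect the study design: singleton AI pregnancies, two embryos
    per IVP transfer, an overgrowth mixture producing roughly a third of IVP
    fetuses above the control 97th percentile at D105, preferential loss of
    IVP females between D56 and D105, and leukocyte libraries at reduced
    sequencing depth.
    """

    seed: int = 0
    day: int = 105  # collection day of the simulated cohort (56 or 105)
    n_ai_dams: int = 12
    n_ivp_dams: int = 36
    embryos_per_ivp_transfer: int = 2
    implantation_prob: float = 0.64
    p_female: float = 0.5
    female_loss_d105: float = 0.30  # IVP-specific excess loss of females after D56
    pi_los: float = 0.30  # probability an IVP fetus draws the overgrowth component
    weight_lognormal_params: dict = field(
        default_factory=lambda: dict(DEFAULT_WEIGHT_PARAMS)
    )
    los_multiplier_params: tuple = (0.262, 0.18)  # (meanlog, sdlog), mean ~1.32
    allometric_exponent: float = 1.0 / 3.0
    measurement_cv: float = 0.05
    growth_divergence_d55: float = 0.25  # LOS multiplier exponent at D55
    n_genes: int = 2000
    n_de_genes: int = 50
    de_log2fc: float = 2.0
    dispersion_params: tuple = (2.0, 0.05)  # gamma (shape, scale), mean phi 0.1
    dam_effect_sd: float = 0.35  # strong enough that samples cluster by animal
    libsize_range: tuple = (5.0e5, 1.5e6)
    ct_noise_sd: float = 0.1  # cycles, for the CT generator

    def validate(self) -> None:
        for name in ("implantation_prob", "p_female", "female_loss_d105", "pi_los"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_ai_dams", "n_ivp_dams", "embryos_per_ivp_transfer",
                     "n_genes", "n_de_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.day not in (56, 105):
            raise ValueError(f"day must be 56 or 105, got {self.day}")
        for name in ("measurement_cv", "dam_effect_sd", "ct_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.los_multiplier_params[1] < 0:
            raise ValueError("los_multiplier_params sdlog must be >= 0")
        if not math.isfinite(self.de_log2fc):
            raise ValueError("de_log2fc must be finite")
        if not self.libsize_range[0] > 0:
            raise ValueError("libsize_range minimum must be positive")
        if self.n_de_genes > self.n_genes:
            raise ValueError(
                f"n_de_genes={self.n_de_genes} exceeds n_genes={self.n_genes}"
            )
        for key in {("M", self.day), ("F", self.day), ("M", 56), ("F", 56)}:
            if key not in self.weight_lognormal_params:
                raise ValueError(f"weight_lognormal_params missing {key}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weight_lognormal_params"] = {
            f"{sex}:{day}": list(v) for (sex, day), v in self.weight_lognormal_params.items()
        }
        return d


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation, for parameter-recovery tests."""

    component: dict = field(default_factory=dict)  # fetus_id -> normal|overgrown
    de_flag: dict = field(default_factory=dict)  # gene -> bool
    log2fc: dict = field(default_factory=dict)  # gene -> planted log2 FC
    dam_effect: dict = field(default_factory=dict)  # dam_id -> log-scale effect
    lib_scaling: dict = field(default_factory=dict)  # sample_id -> expected depth


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[FetusRecord], list[UltrasoundExam], SyntheticTruth]:
    """Generate one collection-day cohort with D55 ultrasound exams.

    AI dams carry singletons; each IVP dam receives
    ``embryos_per_ivp_transfer`` embryos, each implanting independently.
    A fetus's weight is lognormal for its sex and day; with probability
    ``pi_los`` an IVP fetus draws the overgrowth component and its weight is
    multiplied by a lognormal factor > 1 on average.  Every linear biometric
    is ``base x (weight_55 / ref_55)^allometric_exponent x (1 + eps)`` with
    eps ~ Normal(0, measurement_cv); at D55 the overgrowth multiplier enters
    attenuated (raised to ``growth_divergence_d55``), modelling the late
    divergence of LOS growth.  For day-105 cohorts, IVP female fetuses are
    additionally lost with probability ``female_loss_d105`` after sex
    assignment, reproducing the observed female deficit.
    """
    config.validate()
    rng = _rng(config, _STREAM_COHORT)
    day = config.day
    truth = SyntheticTruth()
    records: list[FetusRecord] = []
    exams: list[UltrasoundExam] = []

    ref_w55 = {
        sex: math.exp(
            config.weight_lognormal_params[(sex, 56)][0]
            + 0.5 * config.weight_lognormal_params[(sex, 56)][1] ** 2
        )
        for sex in ("M", "F")
    }

    def add_fetus(fid: str, dam: str, group: str, twin: bool) -> None:
        sex = "F" if rng.random() < config.p_female else "M"
        if group == GROUP_IVP and sex == "F" and day == 105:
            if rng.random() < config.female_loss_d105:
                return  # fetus lost between D56 and D105
        z = rng.standard_normal()
        meanlog, sdlog = config.weight_lognormal_params[(sex, day)]
        meanlog55, sdlog55 = config.weight_lognormal_params[(sex, 56)]
        overgrown = group == GROUP_IVP and rng.random() < config.pi_los
        mult = 1.0
        if overgrown:
            mlog, msd = config.los_multiplier_params
            mult = math.exp(mlog + msd * rng.standard_normal())
        weight = math.exp(meanlog + sdlog * z) * mult
        w55 = math.exp(meanlog55 + sdlog55 * z) * mult ** config.growth_divergence_d55

        scale_coll = (weight / math.exp(meanlog + 0.5 * sdlog ** 2)) ** config.allometric_exponent
        day_shrink = 1.0 if day == 105 else (8.7 / 460.0) ** config.allometric_exponent
        coll = {
            name: base * day_shrink * scale_coll
            * (1.0 + config.measurement_cv * rng.standard_normal())
            for name, base in COLLECTION_BASE_D105.items()
        }
        records.append(
            FetusRecord(
                fetus_id=fid, dam_id=dam, group=group, sex=sex, day=day,
                weight=weight, twin=twin, collection_measurements=coll,
            )
        )
        scale55 = (w55 / ref_w55[sex]) ** config.allometric_exponent
        measurements = {
            name: base * scale55 * (1.0 + config.measurement_cv * rng.standard_normal())
            for name, base in ULTRASOUND_BASE.items()
        }
        exams.append(UltrasoundExam(fetus_id=fid, day=55, **measurements))
        truth.component[fid] = "overgrown" if overgrown else "normal"

    for i in range(config.n_ai_dams):
        add_fetus(f"AI-{i + 1:03d}", f"damA{i + 1:03d}", GROUP_AI, twin=False)
    for i in range(config.n_ivp_dams):
        implanted = [
            rng.random() < config.implantation_prob
            for _ in range(config.embryos_per_ivp_transfer)
        ]
        n_implanted = sum(implanted)
        for k in range(n_implanted):
            add_fetus(
                f"IVP-{i + 1:03d}{chr(ord('A') + k)}",
                f"damV{i + 1:03d}",
                GROUP_IVP,
                twin=n_implanted > 1,
            )
    return records, exams, truth


def simulate_counts(
    config: SimConfig, samples: list[SampleMeta]
) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial gene x sample counts with dam effects.

    counts_gj ~ NB(mean = libsize_j x q_g x exp(dam effect) x 2^(lfc_g if
    sample j's dam is flagged extreme), dispersion phi_g).  The dam effect
    is shared by a dam's D55 and D105 samples, so with a large
    ``dam_effect_sd`` samples pair by animal under euclidean clustering.
    """
    config.validate()
    if not samples:
        raise ValueError("samples must be non-empty")
    rng = _rng(config, _STREAM_COUNTS)
    truth = SyntheticTruth()

    genes = [f"G{g + 1:05d}" for g in range(config.n_genes)]
    log_q = rng.normal(0.0, 1.5, size=config.n_genes)
    q = np.exp(log_q)
    q /= q.sum()
    shape, scale = config.dispersion_params
    phi = rng.gamma(shape, scale, size=config.n_genes)
    phi = np.maximum(phi, 1e-8)

    de_idx = rng.choice(config.n_genes, size=config.n_de_genes, replace=False)
    lfc = np.zeros(config.n_genes)
    lfc[de_idx] = config.de_log2fc
    for g, gene in enumerate(genes):
        truth.de_flag[gene] = bool(lfc[g] != 0.0)
        truth.log2fc[gene] = float(lfc[g])

    # gene-wise random effect per dam (an animal-specific expression
    # profile, shared by the dam's D55 and D105 draws); a scalar per-dam
    # effect would be absorbed by depth normalization and could not make
    # samples cluster by animal.  The effect scale varies by gene (uniform
    # on [0, 2 x dam_effect_sd]), so a subset of genes is stable across
    # animals the way qPCR reference genes are in real data.
    gene_scale = rng.uniform(0.0, 2.0, size=config.n_genes) * config.dam_effect_sd
    dams = sorted({s.dam_id for s in samples})
    dam_u = {d: gene_scale * rng.standard_normal(config.n_genes) for d in dams}
    truth.dam_effect = {d: u.tolist() for d, u in dam_u.items()}

    lo, hi = config.libsize_range
    counts = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        libsize = rng.uniform(lo, hi)
        truth.lib_scaling[s.sample_id] = float(libsize)
        mu = libsize * q * np.exp(dam_u[s.dam_id])
        if s.extreme:
            mu = mu * np.exp2(lfc)
        r = 1.0 / phi
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    cm = CountMatrix(genes, [s.sample_id for s in samples], counts)
    return cm, truth


def simulate_qpcr(
    config: SimConfig,
    fold_truth: dict[str, float],
    target: str = "TARGET1",
    reference_genes: tuple[str, ...] = ("REF1", "REF2", "REF3"),
    target_base_ct: float = 25.0,
    reference_base_ct: float = 20.0,
) -> pd.DataFrame:
    """CT table with planted per-sample fold differences for one target.

    CT_target = base - log2(fold) + noise; reference genes are constant up
    to the same gaussian cycle noise (``ct_noise_sd``).
    """
    config.validate()
    bad = {s: f for s, f in fold_truth.items() if not f > 0}
    if bad:
        raise ValueError(f"non-positive fold for samples {sorted(bad)}")
    rng = _rng(config, _STREAM_QPCR)
    rows = []
    for sample in fold_truth:
        for gene in reference_genes:
            rows.append(
                {
                    "sample_id": sample, "gene": gene,
                    "CT": reference_base_ct + config.ct_noise_sd * rng.standard_normal(),
                    "role": "reference",
                }
            )
        rows.append(
            {
                "sample_id": sample, "gene": target,
                "CT": target_base_ct - math.log2(fold_truth[sample])
                + config.ct_noise_sd * rng.standard_normal(),
                "role": "target",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published-summary fixtures

# (group, sex, n, weight range lo, hi); heaviest animals keep their published ids
_FIXTURE_SPEC = {
    56: {
        "thresholds": {"M": 10.18, "F": 10.16},
        "subgroups": [
            ("AI", "M", 8, 6.21, 10.27),
            ("AI", "F", 6, 6.20, 10.22),
            ("IVP-Normal", "M", 13, 6.94, 9.98),
            ("IVP-LOS", "M", 8, 10.23, 13.77),
            ("IVP-Normal", "F", 21, 5.55, 9.80),
            ("IVP-LOS", "F", 1, 10.31, 10.31),
        ],
        "named_heaviest": {("IVP-LOS", "M"): "584A", ("IVP-LOS", "F"): "678B"},
    },
    105: {
        "thresholds": {"M": 548.92, "F": 463.14},
        "subgroups": [
            ("AI", "M", 8, 442.0, 550.0),
            ("AI", "F", 4, 388.0, 468.0),
            ("IVP-Normal", "M", 25, 366.0, 542.0),
            ("IVP-LOS", "M", 8, 552.0, 1080.0),
            ("IVP-Normal", "F", 4, 318.0, 448.0),
            ("IVP-LOS", "F", 9, 468.0, 986.0),
        ],
        "named_heaviest": {("IVP-LOS", "M"): "664", ("IVP-LOS", "F"): "604B"},
    },
}


def make_published_fixture(day: int) -> tuple[list[FetusRecord], dict[str, float]]:
    """Deterministic cohort matching published subgroup sizes and ranges.

    Weights are evenly spaced within each published subgroup range with the
    endpoints included (synthetic interpolation — the raw per-animal weights
    are not published); the published sex-specific 97th-percentile
    thresholds are returned alongside.  Classifying the fixture with those
    thresholds reproduces the published LOS counts exactly.
    """
    if day not in _FIXTURE_SPEC:
        raise ValueError(f"day must be 56 or 105, got {day}")
    spec = _FIXTURE_SPEC[day]
    records = []
    for group, sex, n, lo, hi in spec["subgroups"]:
        weights = np.linspace(lo, hi, n)
        base_group = GROUP_AI if group == "AI" else GROUP_IVP
        for k, w in enumerate(weights):
            fid = f"D{day}-{group}-{sex}-{k + 1:02d}"
            named = spec["named_heaviest"].get((group, sex))
            if named is not None and k == n - 1:
                fid = named
            records.append(
                FetusRecord(
                    fetus_id=fid, dam_id=f"dam-{fid}", group=base_group,
                    sex=sex, day=day, weight=float(w), twin=False,
                )
            )
    return records, dict(spec["thresholds"])


# fetometry fixture constraints: published control-max product threshold and
# which fetuses lie above it / above the fixed 100 line
_FETOMETRY_SPEC = {
    105: {"control_max": 79.92, "above": {"664": 118.4, "604B": 105.8}},
    56: {"control_max": 91.32, "above": {"584A": 103.5}},
}


def make_fetometry_fixture(
    day: int,
) -> tuple[list[UltrasoundExam], float]:
    """Synthetic D55 exams consistent with the published product summaries.

    The raw six-measurement products are not published; this fixture assigns
    products so that the published constraints hold exactly: the maximum
    control (AI) product equals the published threshold, every non-extreme
    IVP product lies on or below it, and only the published extreme fetuses
    exceed it (and the fixed 100 line).  Products increase with fixture
    weight within each subgroup; the six measurements are back-derived from
    each product through the base-shape proportions, so the product of the
    stored measurements reproduces the assigned product to float precision.
    Returns (exams, published control-max threshold).
    """
    if day not in _FETOMETRY_SPEC:
        raise ValueError(f"day must be 56 or 105, got {day}")
    records, _ = make_published_fixture(day)
    spec = _FETOMETRY_SPEC[day]
    t = spec["control_max"]

    base_product = 1.0
    for name in PRODUCT_MEASUREMENTS:
        base_product *= ULTRASOUND_BASE[name]

    # rank fetuses by weight within AI / IVP and spread products below the
    # threshold; extremes get their published-position products (> 100)
    exams = []
    ai = sorted((r for r in records if r.group == GROUP_AI), key=lambda r: (r.weight, r.fetus_id))
    ivp = sorted((r for r in records if r.group == GROUP_IVP), key=lambda r: (r.weight, r.fetus_id))
    products: dict[str, float] = {}
    for rank, r in enumerate(ai):
        frac = rank / (len(ai) - 1) if len(ai) > 1 else 1.0
        products[r.fetus_id] = t * (0.6 + 0.4 * frac)  # control max hits t exactly
    non_extreme = [r for r in ivp if r.fetus_id not in spec["above"]]
    for rank, r in enumerate(non_extreme):
        frac = rank / (len(non_extreme) - 1) if len(non_extreme) > 1 else 1.0
        products[r.fetus_id] = t * (0.55 + 0.45 * frac)  # on or below the threshold
    products.update(spec["above"])

    reconstructed: dict[str, float] = {}
    for r in records:
        scale = (products[r.fetus_id] / base_product) ** (1.0 / 6.0)
        kwargs = {name: ULTRASOUND_BASE[name] * scale for name in PRODUCT_MEASUREMENTS}
        kwargs["BPD"] = ULTRASOUND_BASE["BPD"]
        exams.append(UltrasoundExam(fetus_id=r.fetus_id, day=55, **kwargs))
        p = 1.0
        for name in PRODUCT_MEASUREMENTS:
            p *= kwargs[name]
        reconstructed[r.fetus_id] = p

    # report the threshold as the max recomputed control product so that
    # screening the stored measurements is float-exact at the boundary
    control_max = max(reconstructed[r.fetus_id] for r in ai)
    return exams, control_max
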