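"""Shared fixtures: small synthetic cohorts and count matrices."""

from __future__ import annotations

import numpy as np
import pytest

from loscreen.leukotranscript.containers import CountMatrix, SampleMeta, meta_frame
from loscreen.synthcohort import SimConfig, simulate_cohort, simulate_counts


@pytest.fixture(scope="session")
def null_counts_small():
    """400 null NB genes, 23 samples, 2 flagged extreme — no true signal."""
    cfg = SimConfig(seed=101, n_genes=400, n_de_genes=0, de_log2fc=0.0, dam_effect_sd=0.0)
    samples = [
        SampleMeta(
            f"S{i:02d}", f"dam{i:02d}", 105,
            "IVP-LOS" if i < 2 else "IVP-Normal", extreme=i < 2,
        )
        for i in range(23)
    ]
    counts, truth = simulate_counts(cfg, samples)
    return counts, meta_frame(samples), truth


@pytest.fixture(scope="session")
def planted_counts():
    """1000 genes with 30 planted 16-fold genes in the two extreme samples."""
    cfg = SimConfig(
        seed=7, n_genes=1000, n_de_genes=30, de_log2fc=4.0,
        dispersion_params=(2.0, 0.025), dam_effect_sd=0.0,
    )
    samples = [
        SampleMeta(
            f"S{i:02d}", f"dam{i:02d}", 105,
            "IVP-LOS" if i < 2 else "IVP-Normal", extreme=i < 2,
        )
        for i in range(23)
    ]
    counts, truth = simulate_counts(cfg, samples)
    return counts, meta_frame(samples), truth


@pytest.fixture(scope="session")
def paired_dam_counts():
    """23 dams x 2 draw days with strong animal-specific expression profiles."""
    cfg = SimConfig(seed=5, n_genes=500, n_de_genes=0, dam_effect_sd=0.5)
    samples = []
    for d in range(23):
        for day in (55, 105):
            samples.append(
                SampleMeta(f"dam{d:02d}-D{day}", f"dam{d:02d}", day, "IVP-Normal")
            )
    counts, _ = simulate_counts(cfg, samples)
    return counts, samples


@pytest.fixture(scope="session")
def large_null_cohort():
    """Large D105 cohort with the overgrowth component switched off."""
    cfg = SimConfig(
        seed=11, day=105, n_ai_dams=3000, n_ivp_dams=2000,
        pi_los=0.0, female_loss_d105=0.0,
    )
    records, exams, truth = simulate_cohort(cfg)
    return records, exams, truth
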