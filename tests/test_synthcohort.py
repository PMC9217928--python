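"""The synthetic-cohort generator: determinism, marginals, fixtures."""

import io
import math

import numpy as np
import pytest

from loscreen.phenotyping import classify_los, los_prevalence
from loscreen.pipeline_io import write_morphometry_csv, write_ultrasound_csv
from loscreen.synthcohort import (
    DEFAULT_WEIGHT_PARAMS,
    ULTRASOUND_BASE,
    SimConfig,
    SyntheticTruth,
    make_fetometry_fixture,
    make_published_fixture,
    simulate_cohort,
    simulate_counts,
)
from loscreen.leukotranscript.containers import SampleMeta


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value, match",
        [
            ("pi_los", 1.5, "pi_los"),
            ("implantation_prob", -0.1, "implantation_prob"),
            ("measurement_cv", -1.0, "measurement_cv"),
            ("de_log2fc", float("nan"), "de_log2fc"),
            ("libsize_range", (0.0, 10.0), "libsize_range"),
            ("day", 77, "day"),
        ],
    )
    def test_offending_field_named(self, field, value, match):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ValueError, match=match):
            cfg.validate()

    def test_too_many_de_genes_rejected(self):
        with pytest.raises(ValueError, match="n_de_genes"):
            SimConfig(n_genes=10, n_de_genes=11).validate()


class TestDeterminism:
    def test_cohort_tables_byte_identical(self):
        cfg = SimConfig(seed=33, n_ai_dams=6, n_ivp_dams=8)
        outputs = []
        for _ in range(2):
            records, exams, _ = simulate_cohort(cfg)
            buf_m, buf_u = io.StringIO(), io.StringIO()
            write_morphometry_csv(records, buf_m)
            write_ultrasound_csv(exams, buf_u)
            outputs.append((buf_m.getvalue(), buf_u.getvalue()))
        assert outputs[0] == outputs[1]

    def test_count_matrix_identical(self):
        cfg = SimConfig(seed=33, n_genes=50)
        samples = [SampleMeta("s1", "d1", 105, "IVP-Normal"),
                   SampleMeta("s2", "d2", 105, "IVP-Normal")]
        c1, _ = simulate_counts(cfg, samples)
        c2, _ = simulate_counts(cfg, samples)
        assert np.array_equal(c1.counts, c2.counts)

    def test_gene_stream_independent_of_cohort_stream(self):
        """Named substreams: the cohort is unchanged when n_genes changes."""
        r1, _, _ = simulate_cohort(SimConfig(seed=4, n_genes=100))
        r2, _, _ = simulate_cohort(SimConfig(seed=4, n_genes=5000))
        assert [(r.fetus_id, r.weight) for r in r1] == [(r.fetus_id, r.weight) for r in r2]


class TestCohortStructure:
    def test_ai_singletons_ivp_up_to_two(self):
        records, _, _ = simulate_cohort(SimConfig(seed=2, n_ai_dams=50, n_ivp_dams=50))
        per_dam = {}
        for r in records:
            per_dam.setdefault(r.dam_id, []).append(r)
        for dam, fetuses in per_dam.items():
            if fetuses[0].group == "AI":
                assert len(fetuses) == 1 and not fetuses[0].twin
            else:
                assert 1 <= len(fetuses) <= 2

    def test_truth_labels_cover_cohort(self):
        records, _, truth = simulate_cohort(SimConfig(seed=2, n_ai_dams=20, n_ivp_dams=20))
        assert set(truth.component) == {r.fetus_id for r in records}

    def test_null_flag_rate_near_three_percent(self, large_null_cohort):
        """With the overgrowth component off, the fraction of IVP fetuses at
        or above the control 97th percentile is ~3% (threshold-estimation
        noise widens the Monte-Carlo band)."""
        records, _, _ = large_null_cohort
        prevalence = los_prevalence(classify_los(records))
        assert 0.015 <= prevalence <= 0.05

    def test_sex_ratio_unbiased_without_loss(self, large_null_cohort):
        records, _, _ = large_null_cohort
        frac_female = np.mean([r.sex == "F" for r in records])
        n = len(records)
        assert abs(frac_female - 0.5) < 3 * math.sqrt(0.25 / n) + 0.01

    def test_female_loss_depletes_ivp_females(self):
        cfg = SimConfig(seed=9, day=105, n_ai_dams=200, n_ivp_dams=600,
                        female_loss_d105=0.5)
        records, _, _ = simulate_cohort(cfg)
        ivp = [r for r in records if r.group == "IVP"]
        frac_female = np.mean([r.sex == "F" for r in ivp])
        assert frac_female < 0.40

    def test_log_weight_marginals_match_config(self, large_null_cohort):
        """Empirical mean/SD of log weight within 3 SE of the lognormal
        parameters, per sex."""
        records, _, _ = large_null_cohort
        for sex in "MF":
            logs = np.log([r.weight for r in records if r.sex == sex and r.group == "AI"])
            meanlog, sdlog = DEFAULT_WEIGHT_PARAMS[(sex, 105)]
            n = logs.size
            assert abs(logs.mean() - meanlog) < 3 * sdlog / math.sqrt(n)
            assert abs(logs.std(ddof=1) - sdlog) < 3 * sdlog / math.sqrt(2 * (n - 1))

    def test_zero_noise_biometrics_exact(self):
        """With noise and overgrowth off, each biometric equals base x
        (D55 weight / reference weight)^(1/3) exactly."""
        cfg = SimConfig(seed=1, measurement_cv=0.0, pi_los=0.0,
                        n_ai_dams=5, n_ivp_dams=5, female_loss_d105=0.0)
        records, exams, _ = simulate_cohort(cfg)
        by_id = {r.fetus_id: r for r in records}
        for exam in exams:
            rec = by_id[exam.fetus_id]
            ml105, sd105 = cfg.weight_lognormal_params[(rec.sex, 105)]
            ml55, sd55 = cfg.weight_lognormal_params[(rec.sex, 56)]
            z = (math.log(rec.weight) - ml105) / sd105
            w55 = math.exp(ml55 + sd55 * z)
            ref = math.exp(ml55 + 0.5 * sd55 ** 2)
            expected = ULTRASOUND_BASE["CRL"] * (w55 / ref) ** cfg.allometric_exponent
            assert exam.CRL == pytest.approx(expected, rel=1e-9)


class TestCountsGenerator:
    def test_de_flags_count(self):
        cfg = SimConfig(seed=3, n_genes=100, n_de_genes=7)
        samples = [SampleMeta("s1", "d1", 105, "IVP-Normal"),
                   SampleMeta("s2", "d2", 105, "IVP-Normal")]
        _, truth = simulate_counts(cfg, samples)
        assert sum(truth.de_flag.values()) == 7

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_counts(SimConfig(seed=0), [])

    def test_counts_nonnegative_integer(self):
        cfg = SimConfig(seed=3, n_genes=60)
        samples = [SampleMeta(f"s{i}", f"d{i}", 105, "IVP-Normal") for i in range(4)]
        counts, _ = simulate_counts(cfg, samples)
        assert counts.counts.dtype.kind == "i" and (counts.counts >= 0).all()


class TestPublishedFixtures:
    def test_d105_subgroup_counts(self):
        records, _ = make_published_fixture(105)
        ai = [r for r in records if r.group == "AI"]
        ivp = [r for r in records if r.group == "IVP"]
        assert len(ai) == 12 and len(ivp) == 46
        assert sum(1 for r in ai if r.sex == "M") == 8
        assert sum(1 for r in ivp if r.sex == "F") == 13

    def test_d56_counts(self):
        records, _ = make_published_fixture(56)
        assert sum(1 for r in records if r.group == "IVP") == 43
        assert len(records) == 57

    def test_range_endpoints_conserved(self):
        records, _ = make_published_fixture(105)
        ai_m = sorted(r.weight for r in records if r.group == "AI" and r.sex == "M")
        assert ai_m[0] == 442.0 and ai_m[-1] == 550.0
        ivp_f = sorted(r.weight for r in records if r.group == "IVP" and r.sex == "F")
        assert ivp_f[0] == 318.0 and ivp_f[-1] == 986.0

    def test_classification_reproduces_published_counts(self):
        records, thresholds = make_published_fixture(105)
        labels = classify_los(records, thresholds=thresholds)
        assert sum(1 for v in labels.labels.values() if v == "IVP-LOS") == 17

    def test_heaviest_keep_published_ids(self):
        records, _ = make_published_fixture(105)
        weights = {r.fetus_id: r.weight for r in records}
        assert weights["664"] == 1080.0 and weights["604B"] == 986.0

    def test_fetometry_thresholds(self):
        _, t105 = make_fetometry_fixture(105)
        _, t56 = make_fetometry_fixture(56)
        assert t105 == pytest.approx(79.92)
        assert t56 == pytest.approx(91.32)

    def test_invalid_day_rejected(self):
        with pytest.raises(ValueError):
            make_published_fixture(77)
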