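"""Negative-binomial LRT engine, BH adjustment, dispersion estimation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from loscreen.leukotranscript import bh_adjust, nb_lrt
from loscreen.leukotranscript.containers import CountMatrix
from loscreen.leukotranscript.deglm import (
    _irls_fit,
    _nb_deviance,
    backend_offsets,
    design_matrix,
    estimate_dispersion,
)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_textbook_pair(self):
        assert bh_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_minimum_over_tail_rule(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_order_preserving_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_step_up_definition(self, p):
        """adjusted_i = min over p_(j) >= p_(i) of m p_(j) / j, capped at 1."""
        p = np.asarray(p)
        m = p.size
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        for i in range(m):
            rank_i = int(np.flatnonzero(order == i)[0]) + 1
            tail = [m * p[order[j - 1]] / j for j in range(rank_i, m + 1)]
            expected[i] = min(1.0, min(tail))
        assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(adj, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestIrlsAgainstStatsmodels:
    def test_deviance_matches_glm_fit(self):
        """The hand-rolled IRLS agrees with statsmodels' NB GLM at fixed
        dispersion, on coefficients and deviance."""
        rng = np.random.default_rng(12)
        n = 30
        x = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        offset = np.log(rng.uniform(0.8, 1.2, n))
        mu_true = np.exp(3.0 + 0.7 * x[:, 1] + offset)
        phi = 0.1
        y = rng.negative_binomial(1 / phi, (1 / phi) / (1 / phi + mu_true)).astype(float)

        beta, mu = _irls_fit(y, x, offset, phi)
        ref = sm.GLM(
            y, x, family=sm.families.NegativeBinomial(alpha=phi), offset=offset
        ).fit()
        assert beta == pytest.approx(ref.params, abs=1e-6)
        assert _nb_deviance(y, mu, phi) == pytest.approx(ref.deviance, rel=1e-6)


class TestDispersion:
    def test_recovers_known_dispersion_on_average(self):
        """Cox-Reid gene-wise estimates center near the simulated value."""
        rng = np.random.default_rng(3)
        n, phi_true = 40, 0.15
        x = np.ones((n, 1))
        offset = np.zeros(n)
        estimates = []
        for _ in range(60):
            mu = 500.0
            y = rng.negative_binomial(
                1 / phi_true, (1 / phi_true) / (1 / phi_true + mu), size=n
            )
            estimates.append(estimate_dispersion(y.astype(float), x, offset))
        assert np.median(estimates) == pytest.approx(phi_true, rel=0.35)


class TestNbLrt:
    def test_all_zero_gene_p_one(self, null_counts_small):
        counts, meta, _ = null_counts_small
        zeroed = counts.counts.copy()
        zeroed[0, :] = 0
        cm = CountMatrix(counts.gene_ids[:50], counts.sample_ids, zeroed[:50])
        table = nb_lrt(cm, meta, ["extreme"], [], backend="B")
        g0 = counts.gene_ids[0]
        assert table.loc[g0, "p"] == 1.0
        assert table.loc[g0, "log2FC"] == 0.0
        assert bool(table.loc[g0, "untestable"])

    def test_non_nested_designs_rejected(self, null_counts_small):
        counts, meta, _ = null_counts_small
        with pytest.raises(ValueError, match="nested"):
            nb_lrt(counts, meta, ["extreme"], ["group"])

    def test_statistic_nonnegative_and_adjp_dominates_p(self, planted_counts):
        counts, meta, _ = planted_counts
        sub = CountMatrix(counts.gene_ids[:100], counts.sample_ids, counts.counts[:100])
        table = nb_lrt(sub, meta, ["extreme"], [], backend="A")
        assert (table["lrt_stat"] >= 0).all()
        assert (table["adj_p"] >= table["p"] - 1e-12).all()

    def test_null_pvalues_near_uniform(self, null_counts_small):
        """Type-I calibration: with no true signal the p-value distribution
        is uniform (KS test) and rejections are monotone in alpha."""
        counts, meta, _ = null_counts_small
        table = nb_lrt(counts, meta, ["extreme"], [], backend="A")
        p = table.loc[~table["untestable"], "p"]
        assert kstest(p, "uniform").pvalue > 0.01
        rej = [int((p <= a).sum()) for a in (0.01, 0.05, 0.10, 0.20)]
        assert rej == sorted(rej)

    def test_planted_genes_rank_first(self, planted_counts):
        """16-fold planted genes in the 2 extreme samples dominate the
        p-value ranking against 21 unaffected samples."""
        counts, meta, truth = planted_counts
        table = nb_lrt(counts, meta, ["extreme"], [], backend="A")
        de_genes = [g for g, f in truth.de_flag.items() if f]
        null_genes = [g for g, f in truth.de_flag.items() if not f]
        null_median = table.loc[null_genes, "p"].median()
        assert (table.loc[de_genes, "p"] < null_median).all()
        assert (table.loc[de_genes, "log2FC"].median()) == pytest.approx(4.0, abs=0.8)

    def test_backends_agree_on_strong_signal(self, planted_counts):
        counts, meta, truth = planted_counts
        sub = CountMatrix(counts.gene_ids[:300], counts.sample_ids, counts.counts[:300])
        ta = nb_lrt(sub, meta, ["extreme"], [], backend="A")
        tb = nb_lrt(sub, meta, ["extreme"], [], backend="B")
        de = [g for g in sub.gene_ids if truth.de_flag[g]]
        if de:
            assert (ta.loc[de, "adj_p"] <= 0.05).mean() > 0.8
            assert (tb.loc[de, "adj_p"] <= 0.05).mean() > 0.8


class TestDesignMatrix:
    def test_treatment_coding(self):
        meta = pd.DataFrame({"group": ["a", "b", "b"], "extreme": [False, False, True]})
        x = design_matrix(meta, ["group", "extreme"])
        assert x.shape == (3, 3)
        assert np.array_equal(x[:, 0], [1, 1, 1])

    def test_rank_deficiency_rejected(self):
        meta = pd.DataFrame({"g1": ["a", "b"], "g2": ["x", "y"]})
        with pytest.raises(ValueError, match="rank"):
            design_matrix(meta, ["g1", "g2"])


def test_backend_offsets_track_depth(null_counts_small):
    """Both backends' offsets rise with sequencing depth."""
    counts, _, truth = null_counts_small
    depth = np.array([truth.lib_scaling[s] for s in counts.sample_ids])
    for backend in ("A", "B"):
        off = backend_offsets(counts, backend)
        r = np.corrcoef(np.log(depth), off)[0, 1]
        assert r > 0.95
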