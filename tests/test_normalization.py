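"""Size-factor methods: median-of-ratios, TMM, upper-quartile."""

import numpy as np
import pytest

from loscreen.leukotranscript import (
    normalize,
    size_factors_mor,
    tmm_factors,
    upperquartile_factors,
)
from loscreen.leukotranscript.containers import CountMatrix


def _cm(counts, genes=None, samples=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(genes, samples, counts)


@pytest.fixture(scope="module")
def random_counts():
    rng = np.random.default_rng(17)
    return _cm(rng.negative_binomial(5, 0.01, size=(300, 6)))


class TestMedianOfRatios:
    def test_identical_samples(self):
        cm = _cm(np.tile([[4], [10], [7]], (1, 4)))
        assert all(f == pytest.approx(1.0) for f in size_factors_mor(cm).factors.values())

    def test_two_sample_hand_case(self):
        """Genes (2,4) vs (8,16): geomeans (4, 8), ratio medians 0.5 and 2."""
        cm = _cm([[2, 8], [4, 16]])
        factors = size_factors_mor(cm).factors
        assert factors["s0"] == pytest.approx(0.5)
        assert factors["s1"] == pytest.approx(2.0)

    def test_exact_scaling_property(self, random_counts):
        """Multiplying one sample by c multiplies its factor, relative to
        every other sample, by exactly c.  (Size factors are defined up to a
        common scale: the per-gene geometric-mean reference contains the
        scaled sample, so only factor ratios are gauge-invariant.)"""
        base = size_factors_mor(random_counts).factors
        scaled = random_counts.counts.copy().astype(float)
        scaled[:, 2] *= 3.0
        new = size_factors_mor(_cm(scaled)).factors
        for j in (0, 1, 3, 4, 5):
            ratio_new = new["s2"] / new[f"s{j}"]
            ratio_old = base["s2"] / base[f"s{j}"]
            assert ratio_new == pytest.approx(3.0 * ratio_old, rel=1e-12)

    def test_duplicated_sample_at_double_depth(self):
        """A sample whose counts are exactly twice another's gets exactly
        twice its factor."""
        rng = np.random.default_rng(23)
        base = rng.integers(1, 300, size=(100, 3))
        counts = np.column_stack([base, base[:, 0] * 2])
        factors = size_factors_mor(_cm(counts)).factors
        assert factors["s3"] == pytest.approx(2.0 * factors["s0"], rel=1e-12)

    def test_no_all_positive_gene_rejected(self):
        cm = _cm([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="no reference genes"):
            size_factors_mor(cm)


class TestUpperQuartile:
    def test_identical_samples(self):
        cm = _cm(np.tile([[4], [10], [7]], (1, 3)))
        assert all(f == pytest.approx(1.0) for f in upperquartile_factors(cm).factors.values())

    def test_hand_case(self):
        """Positive-count upper quartiles (50, 200): factors (0.5, 2)."""
        cm = _cm([[10, 40], [20, 80], [30, 120], [50, 200], [60, 240]])
        factors = upperquartile_factors(cm).factors
        assert factors["s0"] == pytest.approx(0.5)
        assert factors["s1"] == pytest.approx(2.0)

    def test_scaling_one_sample(self, random_counts):
        base = upperquartile_factors(random_counts)
        scaled = random_counts.counts.copy().astype(float)
        scaled[:, 0] *= 5.0
        new = upperquartile_factors(_cm(scaled))
        # u_0 scales by 5 exactly; all factors share the new geomean
        ratio = np.array(
            [new.factors[s] / base.factors[s] for s in random_counts.sample_ids]
        )
        assert ratio[0] / ratio[1] == pytest.approx(5.0, rel=1e-12)

    def test_geometric_mean_one(self, random_counts):
        factors = np.array(list(upperquartile_factors(random_counts).factors.values()))
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, rel=1e-12)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="s1"):
            upperquartile_factors(_cm([[1, 0], [2, 0]]))


class TestTMM:
    def test_identical_samples(self):
        cm = _cm(np.tile([[40], [100], [70], [10]], (1, 3)))
        assert all(f == pytest.approx(1.0) for f in tmm_factors(cm).factors.values())

    def test_geometric_mean_one(self, random_counts):
        factors = np.array(list(tmm_factors(random_counts).factors.values()))
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, rel=1e-12)

    def test_pure_depth_scaling_gives_unit_factors(self):
        """Sample 2 = 4 x sample 1: library proportions are identical, so the
        composition correction is 1 for both (depth lives in library size)."""
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, size=200)
        cm = _cm(np.column_stack([base, base * 4]))
        factors = tmm_factors(cm).factors
        assert factors["s0"] == pytest.approx(1.0)
        assert factors["s1"] == pytest.approx(1.0)

    def test_composition_shift_detected(self):
        """A sample with a small set of strongly amplified genes gets a
        factor < 1: its depth overstates the expression of the unchanged
        majority, which the trimmed mean of M-values corrects."""
        rng = np.random.default_rng(1)
        base = rng.integers(100, 400, size=400)
        shifted = base.copy()
        shifted[:40] = shifted[:40] * 16
        cm = _cm(np.column_stack([base, shifted]))
        factors = tmm_factors(cm).factors
        assert factors["s1"] < 1.0 < factors["s0"]

    def test_permutation_invariance(self, random_counts):
        base = tmm_factors(random_counts).factors
        rng = np.random.default_rng(2)
        perm = rng.permutation(random_counts.n_genes)
        shuffled = _cm(
            random_counts.counts[perm],
            genes=[random_counts.gene_ids[i] for i in perm],
            samples=random_counts.sample_ids,
        )
        new = tmm_factors(shuffled).factors
        for s in random_counts.sample_ids:
            assert new[s] == pytest.approx(base[s], rel=1e-12)

    def test_disjoint_support_warns(self):
        cm = _cm([[5, 0], [8, 0], [0, 7], [0, 9]])
        with pytest.warns(UserWarning, match="no positive genes"):
            factors = tmm_factors(cm).factors
        assert all(f == pytest.approx(1.0) for f in factors.values())


class TestNormalize:
    def test_unit_factors_identity(self, random_counts):
        sf = size_factors_mor(_cm(np.tile([[4], [10], [7]], (1, 6))))
        out = normalize(random_counts, sf)
        assert np.allclose(out, random_counts.counts)

    def test_factor_two_halves_column(self, random_counts):
        sf = size_factors_mor(random_counts)
        out = normalize(random_counts, sf)
        j = 3
        expected = random_counts.counts[:, j] / sf.factors["s3"]
        assert np.allclose(out[:, j], expected)

    def test_recovers_equal_upper_quartiles(self):
        """Dividing by true scalings equalizes the column upper quartiles."""
        rng = np.random.default_rng(9)
        base = rng.negative_binomial(5, 0.01, size=(500, 4)).astype(float)
        scalings = np.array([0.5, 1.0, 2.0, 4.0])
        cm = _cm(np.rint(base * 200 * scalings).astype(int))
        sf = upperquartile_factors(cm)
        out = normalize(cm, sf)
        uqs = [np.quantile(out[:, j][out[:, j] > 0], 0.75) for j in range(4)]
        assert max(uqs) / min(uqs) < 1.1

    def test_missing_factor_rejected(self, random_counts):
        from loscreen.leukotranscript.containers import SizeFactorSet

        sf = SizeFactorSet("median-of-ratios", {"s0": 1.0})
        with pytest.raises(ValueError, match="no size factor"):
            normalize(random_counts, sf)
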