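"""Count normalization: median-of-ratios, TMM and upper-quartile size factors."""

from __future__ import annotations

import warnings

import numpy as np

from .containers import CountMatrix, SizeFactorSet


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def size_factors_mor(counts: CountMatrix) -> SizeFactorSet:
    """Median-of-ratios size factors.

    For each gene with positive counts in every sample, compute the ratio of
    each sample's count to the gene's geometric mean; the sample's factor is
    the median of those ratios.  Exact property: scaling one sample's counts
    by c scales its factor by c.
    """
    c = counts.counts.astype(float)
    all_positive = np.all(c > 0, axis=1)
    if not np.any(all_positive):
        raise ValueError("no reference genes for geometric means (no all-positive gene)")
    logc = np.log(c[all_positive])
    log_geomean = logc.mean(axis=1, keepdims=True)
    log_factors = np.median(logc - log_geomean, axis=0)
    return SizeFactorSet(
        method="median-of-ratios",
        factors=dict(zip(counts.sample_ids, np.exp(log_factors))),
    )


def upperquartile_factors(counts: CountMatrix) -> SizeFactorSet:
    """Upper-quartile size factors, rescaled to geometric mean 1.

    u_j = 75th percentile (type 7) of sample j's positive counts;
    s_j = u_j / geomean(u).
    """
    c = counts.counts.astype(float)
    u = np.empty(counts.n_samples)
    for j in range(counts.n_samples):
        positive = c[:, j][c[:, j] > 0]
        if positive.size == 0:
            raise ValueError(f"sample {counts.sample_ids[j]!r} has no positive counts")
        u[j] = np.quantile(positive, 0.75, method="linear")
    factors = u / _geomean(u)
    return SizeFactorSet(
        method="upper-quartile", factors=dict(zip(counts.sample_ids, factors))
    )


def tmm_factors(counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> SizeFactorSet:
    """Trimmed-mean-of-M-values composition factors (geometric mean 1).

    The reference sample is the one whose library-size-scaled upper quartile
    of positive counts is closest to the mean of those quantities.  For each
    sample, gene-wise log2 ratios of library proportions versus the
    reference (M) and average log2 abundances (A) are computed over genes
    positive in both; the central portion after trimming ``trim_m`` of M and
    ``trim_a`` of A (both tails each) is averaged with precision weights
    from the asymptotic binomial variance.  A sample sharing no positive
    gene with the reference gets factor 1 with a warning.
    """
    c = counts.counts.astype(float)
    lib = c.sum(axis=0)
    if np.any(lib <= 0):
        j = int(np.argmin(lib))
        raise ValueError(f"sample {counts.sample_ids[j]!r} has zero library size")

    uq = np.empty(counts.n_samples)
    for j in range(counts.n_samples):
        positive = c[:, j][c[:, j] > 0]
        uq[j] = np.quantile(positive, 0.75, method="linear") / lib[j] if positive.size else 0.0
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(counts.n_samples)
    for j in range(counts.n_samples):
        if j == ref:
            continue
        both = (c[:, j] > 0) & (c[:, ref] > 0)
        if not np.any(both):
            warnings.warn(
                f"sample {counts.sample_ids[j]!r} shares no positive genes with "
                f"the TMM reference; factor set to 1",
                stacklevel=2,
            )
            continue
        y, r = c[both, j], c[both, ref]
        pj, pr = y / lib[j], r / lib[ref]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        # precision weights: inverse asymptotic variance of M under binomial sampling
        w = (lib[j] - y) / (lib[j] * y) + (lib[ref] - r) / (lib[ref] * r)

        keep = _double_trim_mask(m, a, trim_m, trim_a)
        if not np.any(keep):
            keep = np.ones_like(m, dtype=bool)
        log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])

    factors = 2.0 ** log_factors
    factors /= _geomean(factors)
    return SizeFactorSet(method="TMM", factors=dict(zip(counts.sample_ids, factors)))


def _double_trim_mask(m: np.ndarray, a: np.ndarray, trim_m: float, trim_a: float) -> np.ndarray:
    """Keep genes inside the central (1-2*trim) rank band of both M and A."""
    n = m.size
    keep = np.ones(n, dtype=bool)
    for values, trim in ((m, trim_m), (a, trim_a)):
        lo = np.floor(n * trim) + 1
        hi = n + 1 - lo
        ranks = np.argsort(np.argsort(values, kind="stable"), kind="stable") + 1
        keep &= (ranks >= lo) & (ranks <= hi)
    return keep


def normalize(counts: CountMatrix, s: SizeFactorSet, log2: bool = False) -> np.ndarray:
    """Divide each sample's counts by its size factor; optional log2(x+1)."""
    factors = s.as_array(counts.sample_ids)
    out = counts.counts.astype(float) / factors[np.newaxis, :]
    if log2:
        out = np.log2(out + 1.0)
    return out
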