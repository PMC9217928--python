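"""Negative-binomial GLM likelihood-ratio differential expression.

One NB log-linear engine serves two backend configurations that mirror the
two mainstream RNA-seq DE frameworks:

* backend ``A`` — upper-quartile between-lane depth step followed by TMM
  composition offsets; gene-wise Cox-Reid dispersions shrunk toward the
  common (all-gene) value on the log scale with a prior weight of 10
  residual-df equivalents.
* backend ``B`` — median-of-ratios size-factor offsets; gene-wise
  dispersions used as estimated (no shrinkage).

For each gene a NB GLM ``log mu = X beta + offset`` is fitted by IRLS with
fixed dispersion under both the full and the reduced (nested) design; the
likelihood-ratio statistic is the deviance difference, referred to a
chi-square with df = difference in design ranks.  P-values are adjusted by
Benjamini-Hochberg.  Genes with all-zero counts are untestable by
convention: p = 1, log2FC = 0, so that the gene universe stays aligned
across backends.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

from .containers import CountMatrix, SizeFactorSet
from .normalization import size_factors_mor, tmm_factors, upperquartile_factors

_LN2 = np.log(2.0)
_PHI_MIN, _PHI_MAX = 1e-8, 10.0


# ---------------------------------------------------------------------------
# design matrices and offsets

def design_matrix(meta: pd.DataFrame, factors: list[str]) -> np.ndarray:
    """Intercept + treatment-coded dummies for the given metadata columns."""
    cols = [np.ones(len(meta))]
    for f in factors:
        values = meta[f]
        if values.dtype == bool or values.dtype.kind in "if":
            levels = sorted(values.unique())
        else:
            levels = sorted(values.astype(str).unique())
            values = values.astype(str)
        for lev in levels[1:]:  # first level is the baseline
            cols.append((values == lev).to_numpy().astype(float))
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"design from factors {factors} is rank-deficient")
    return x


def backend_offsets(counts: CountMatrix, backend: str) -> np.ndarray:
    """log effective library size per sample for a backend.

    Backend A: the upper-quartile factor carries sequencing depth, the TMM
    factor (computed on the upper-quartile-equalized counts) the residual
    composition correction.  Backend B: the median-of-ratios factor carries
    both.
    """
    if backend == "A":
        uq = upperquartile_factors(counts).as_array(counts.sample_ids)
        equalized = CountMatrix(
            counts.gene_ids,
            counts.sample_ids,
            np.rint(counts.counts / uq[np.newaxis, :]).astype(np.int64),
        )
        tmm = tmm_factors(equalized).as_array(counts.sample_ids)
        return np.log(uq * tmm)
    if backend == "B":
        mor = size_factors_mor(counts).as_array(counts.sample_ids)
        return np.log(mor)
    raise ValueError(f"unknown backend {backend!r}")


def offsets_from_size_factors(counts: CountMatrix, s: SizeFactorSet) -> np.ndarray:
    """Offsets (log effective depth) implied by one size-factor set."""
    f = s.as_array(counts.sample_ids)
    if s.method == "TMM":
        lib = counts.counts.sum(axis=0).astype(float)
        eff = lib * f
        eff /= np.exp(np.mean(np.log(eff)))
        return np.log(eff)
    return np.log(f)


# ---------------------------------------------------------------------------
# per-gene NB fitting

def _irls_fit(
    y: np.ndarray, x: np.ndarray, offset: np.ndarray, phi: float,
    max_iter: int = 50, tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit log mu = x beta + offset with NB variance mu + phi mu^2.

    Returns (beta, mu).  Standard IRLS with working response
    z = eta + (y - mu) / mu and weights mu / (1 + phi mu).
    """
    mu = np.maximum(y, 0.5).astype(float)
    eta = np.log(mu)
    beta = np.zeros(x.shape[1])
    dev = _nb_deviance(y, mu, phi)
    for _ in range(max_iter):
        w = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        xw = x * w[:, np.newaxis]
        beta_new = np.linalg.solve(xw.T @ x, xw.T @ z)
        eta = x @ beta_new + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        dev_new = _nb_deviance(y, mu, phi)
        beta = beta_new
        if abs(dev_new - dev) < tol * (abs(dev) + 1.0):
            dev = dev_new
            break
        dev = dev_new
    return beta, mu


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """2 x (saturated log-lik - model log-lik) for fixed dispersion phi."""
    if phi < _PHI_MIN:
        # Poisson limit
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(term - (y - mu)))
    r = 1.0 / phi
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    term2 = (y + r) * np.log((mu + r) / (y + r))
    return float(2.0 * np.sum(term1 + term2))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    if phi < _PHI_MIN:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
    )


def _cox_reid_apl(y: np.ndarray, x: np.ndarray, offset: np.ndarray, phi: float) -> float:
    """Cox-Reid adjusted profile log-likelihood of the dispersion."""
    _, mu = _irls_fit(y, x, offset, phi)
    w = mu / (1.0 + phi * mu)
    xtwx = (x * w[:, np.newaxis]).T @ x
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    return _nb_loglik(y, mu, phi) - 0.5 * logdet


def estimate_dispersion(y: np.ndarray, x: np.ndarray, offset: np.ndarray) -> float:
    """Gene-wise Cox-Reid APL maximum over log-dispersion."""
    res = minimize_scalar(
        lambda lp: -_cox_reid_apl(y, x, offset, np.exp(lp)),
        bounds=(np.log(_PHI_MIN), np.log(_PHI_MAX)),
        method="bounded",
        options={"xatol": 0.05},
    )
    return float(np.exp(res.x))


def estimate_common_dispersion(
    counts: np.ndarray, x: np.ndarray, offsets: np.ndarray, max_genes: int = 1000
) -> float:
    """All-gene dispersion maximizing the summed Cox-Reid APL.

    For large panels an evenly spaced subset of ``max_genes`` genes is used;
    the subset is deterministic, so repeated runs agree.
    """
    n_genes = counts.shape[0]
    if n_genes > max_genes:
        idx = np.linspace(0, n_genes - 1, max_genes).astype(int)
        counts = counts[idx]

    def neg_sum_apl(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        return -sum(_cox_reid_apl(y, x, offsets, phi) for y in counts)

    res = minimize_scalar(
        neg_sum_apl,
        bounds=(np.log(_PHI_MIN), np.log(_PHI_MAX)),
        method="bounded",
        options={"xatol": 0.01},
    )
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# the LRT across genes

def nb_lrt(
    counts: CountMatrix,
    meta: pd.DataFrame,
    full: list[str],
    reduced: list[str],
    backend: str = "A",
    offsets: np.ndarray | None = None,
    dispersion_prior_weight: float | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test of ``full`` vs ``reduced`` factors per gene.

    ``meta`` must be indexed consistently with ``counts.sample_ids`` and
    contain every factor column.  Returns a DataFrame indexed by gene with
    columns baseMean, log2FC, lrt_stat, df, p, adj_p, dispersion, backend.
    """
    if not set(reduced) <= set(full):
        raise ValueError(f"designs not nested: reduced {reduced} not within full {full}")
    meta = meta.loc[counts.sample_ids]
    x_full = design_matrix(meta, full)
    x_red = design_matrix(meta, reduced)
    df_test = x_full.shape[1] - x_red.shape[1]
    if df_test < 1:
        raise ValueError("full design adds no parameters over the reduced design")

    if offsets is None:
        offsets = backend_offsets(counts, backend)
    offsets = np.asarray(offsets, dtype=float)
    if dispersion_prior_weight is None:
        dispersion_prior_weight = 10.0 if backend == "A" else 0.0

    c = counts.counts.astype(float)
    n, p_full = c.shape[1], x_full.shape[1]
    df_resid = n - p_full
    testable = c.sum(axis=1) > 0

    # gene-wise dispersions under the full design
    phi_gene = np.full(counts.n_genes, np.nan)
    for g in np.flatnonzero(testable):
        phi_gene[g] = estimate_dispersion(c[g], x_full, offsets)

    # common dispersion: maximizer of the summed Cox-Reid APL across genes,
    # the shrinkage target on the log scale
    if np.any(testable):
        log_phi_common = np.log(
            estimate_common_dispersion(c[testable], x_full, offsets)
        )
    else:
        log_phi_common = np.log(_PHI_MIN)
    w0 = float(dispersion_prior_weight)
    if w0 > 0:
        log_phi = (df_resid * np.log(np.maximum(phi_gene, _PHI_MIN)) + w0 * log_phi_common) / (
            df_resid + w0
        )
        phi_used = np.exp(log_phi)
    else:
        phi_used = phi_gene

    base_mean = (c / np.exp(offsets)[np.newaxis, :]).mean(axis=1)
    lfc = np.zeros(counts.n_genes)
    lrt = np.zeros(counts.n_genes)
    pval = np.ones(counts.n_genes)
    for g in np.flatnonzero(testable):
        y, phi = c[g], float(phi_used[g])
        beta_full, mu_full = _irls_fit(y, x_full, offsets, phi)
        _, mu_red = _irls_fit(y, x_red, offsets, phi)
        stat = _nb_deviance(y, mu_red, phi) - _nb_deviance(y, mu_full, phi)
        lrt[g] = max(stat, 0.0)
        pval[g] = chi2.sf(lrt[g], df_test)
        # effect size: first coefficient the full design adds, in log2 units
        lfc[g] = beta_full[x_red.shape[1]] / _LN2

    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": lfc,
            "lrt_stat": lrt,
            "df": df_test,
            "p": pval,
            "adj_p": bh_adjust(pval),
            "dispersion": np.where(np.isnan(phi_gene), 0.0, phi_used),
            "untestable": ~testable,
        },
        index=pd.Index(counts.gene_ids, name="gene"),
    )
    table["backend"] = backend
    return table


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
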