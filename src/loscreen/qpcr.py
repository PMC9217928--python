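"""Comparative-CT (delta-delta-CT) relative quantification.

Each sample's target CT is first normalized to the geometric mean of the
endogenous reference genes (delta CT); the fold difference of a test sample
relative to a baseline group is then 2^-(delta CT_sample - mean delta CT of
the baseline), so that the average fold over the baseline samples is exactly
1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ROLE_TARGET = "target"
ROLE_REFERENCE = "reference"


@dataclass
class QpcrResult:
    """Per-sample fold differences for one target gene."""

    target: str
    reference_genes: list[str]
    delta_ct: pd.Series  # per sample
    baseline_mean_dct: float
    folds: pd.Series  # per sample, 2^-(ddct)


def baseline_mean_fold(result: QpcrResult, baseline: set[str] | list[str]) -> float:
    """Average fold over the baseline group, on the scale the baseline was defined.

    The baseline level is an arithmetic mean of delta-CT values, i.e. a mean
    on the log2 scale of relative quantities; the matching average of folds
    is therefore the geometric mean, which equals 1 exactly for the baseline
    samples themselves (the "average fold difference = 1" convention).
    """
    folds = result.folds.loc[sorted(set(baseline))].to_numpy(dtype=float)
    return float(np.exp(np.mean(np.log(folds))))


def geomean_ct(refs) -> float:
    """Geometric mean of the reference-gene CT values of one sample."""
    refs = np.asarray(refs, dtype=float)
    if refs.size == 0:
        raise ValueError("no reference CT values")
    if np.any(refs <= 0) or not np.all(np.isfinite(refs)):
        raise ValueError("reference CT values must be finite and positive")
    return float(np.exp(np.mean(np.log(refs))))


def ddct_fold(
    table: pd.DataFrame,
    target: str,
    baseline: set[str] | list[str],
    test: set[str] | list[str] | None = None,
    linearized_reference: bool = False,
) -> QpcrResult:
    """Fold differences of ``test`` samples against the ``baseline`` group.

    ``table`` has columns (sample_id, gene, CT, role).  Technical replicate
    CT rows for the same (sample, gene) are averaged arithmetically before
    any computation.  With ``linearized_reference`` the reference level is
    aggregated as -log2(geomean of 2^-CT) (i.e. the arithmetic mean CT)
    instead of the geometric mean of the CT cycle values themselves; the
    two differ by fractions of a cycle for typical CTs.
    """
    baseline = set(baseline)
    test = set(test) if test is not None else set()
    if not baseline:
        raise ValueError("baseline sample set is empty")
    if baseline & test:
        raise ValueError(f"baseline and test overlap: {sorted(baseline & test)}")

    required = {"sample_id", "gene", "CT", "role"}
    if not required <= set(table.columns):
        raise ValueError(f"CT table missing columns {sorted(required - set(table.columns))}")
    if np.any(table["CT"] <= 0) or not np.all(np.isfinite(table["CT"])):
        raise ValueError("CT values must be finite and positive")

    # average technical replicates
    ct = table.groupby(["sample_id", "gene", "role"], as_index=False)["CT"].mean()
    ref_genes = sorted(ct.loc[ct["role"] == ROLE_REFERENCE, "gene"].unique())
    if not ref_genes:
        raise ValueError("no reference genes in the CT table")

    samples = sorted(baseline | test) if test else sorted(ct["sample_id"].unique())
    dct = {}
    for s in samples:
        sub = ct[ct["sample_id"] == s].set_index("gene")["CT"]
        missing = [g for g in ref_genes if g not in sub.index]
        if missing:
            raise ValueError(f"sample {s!r} missing reference gene {missing[0]!r}")
        if target not in sub.index:
            raise ValueError(f"sample {s!r} missing target gene {target!r}")
        if linearized_reference:
            ref_level = float(np.mean(sub.loc[ref_genes]))
        else:
            ref_level = geomean_ct(sub.loc[ref_genes])
        dct[s] = float(sub.loc[target]) - ref_level
    dct = pd.Series(dct, name="delta_ct")

    missing_base = baseline - set(dct.index)
    if missing_base:
        raise ValueError(f"baseline samples absent from table: {sorted(missing_base)}")
    base_mean = float(dct.loc[sorted(baseline)].mean())
    folds = 2.0 ** -(dct - base_mean)
    return QpcrResult(
        target=target,
        reference_genes=ref_genes,
        delta_ct=dct,
        baseline_mean_dct=base_mean,
        folds=folds.rename("fold"),
    )
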