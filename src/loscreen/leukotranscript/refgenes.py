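"""Backend consensus and qPCR reference-gene selection."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ConsensusResult


def consensus(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    contrast: str = "",
) -> ConsensusResult:
    """Genes significant (adj_p <= alpha) in both backends.

    Intersecting the two frameworks' significant sets trades sensitivity
    for robustness of the candidate list; both tables must cover the same
    gene universe.
    """
    genes_a, genes_b = set(table_a.index), set(table_b.index)
    if genes_a != genes_b:
        diff = sorted(genes_a.symmetric_difference(genes_b))
        raise ValueError(f"gene universes differ; symmetric difference: {diff}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    sig_a = set(table_a.index[table_a["adj_p"] <= alpha])
    sig_b = set(table_b.index[table_b["adj_p"] <= alpha])
    return ConsensusResult(
        contrast=contrast, alpha=alpha, significant_a=sig_a, significant_b=sig_b
    )


def select_reference_genes(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    normalized: pd.DataFrame,
    cv_max: float = 0.10,
    min_adj_p_a: float = 0.99,
    min_adj_p_b: float = 0.8,
) -> list[str]:
    """Stably-expressed genes suitable as qPCR normalizers.

    A gene qualifies when it is as far from differential expression as the
    adjustment allows in backend A (adj_p >= ``min_adj_p_a``, the practical
    reading of "FDR = 1"), clearly null in backend B (adj_p > ``min_adj_p_b``)
    and has a coefficient of variation (SD / mean of its normalized counts
    across all samples) <= ``cv_max``.  ``normalized`` is a genes x samples
    DataFrame.  Zero-mean genes are excluded.
    """
    genes = set(table_a.index) & set(table_b.index) & set(normalized.index)
    selected = []
    for g in normalized.index:
        if g not in genes:
            continue
        values = normalized.loc[g].to_numpy(dtype=float)
        mean = values.mean()
        if mean <= 0:
            continue  # zero-mean gene: CV undefined
        cv = values.std(ddof=1) / mean
        if (
            table_a.loc[g, "adj_p"] >= min_adj_p_a
            and table_b.loc[g, "adj_p"] > min_adj_p_b
            and cv <= cv_max
        ):
            selected.append(g)
    return selected
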