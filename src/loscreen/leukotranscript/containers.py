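"""In-memory containers for the count-matrix analytics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self.sample_ids) < 2:
            raise ValueError("need at least 2 samples")
        if np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count for gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleMeta:
    """Annotation of one leukocyte RNA sample (one dam at one blood draw)."""

    sample_id: str
    dam_id: str
    day: int  # 55 or 105
    group: str  # Control-AI / IVP-Normal / IVP-LOS
    n_fetuses: int = 1
    total_fetal_mass: float = float("nan")  # grams
    extreme: bool = False  # dam of one of the two largest LOS fetuses

    def __post_init__(self) -> None:
        if self.extreme and self.group != "IVP-LOS":
            raise ValueError(
                f"sample {self.sample_id}: extreme flag requires group IVP-LOS, "
                f"got {self.group!r}"
            )
        if self.n_fetuses not in (1, 2):
            raise ValueError(f"sample {self.sample_id}: n_fetuses must be 1 or 2")


def meta_frame(samples: list[SampleMeta]) -> pd.DataFrame:
    """Sample metadata as a DataFrame indexed by sample_id."""
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "dam_id": [s.dam_id for s in samples],
            "day": [s.day for s in samples],
            "group": [s.group for s in samples],
            "n_fetuses": [s.n_fetuses for s in samples],
            "total_fetal_mass": [s.total_fetal_mass for s in samples],
            "extreme": [s.extreme for s in samples],
        }
    ).set_index("sample_id", drop=False)
    return df


@dataclass
class SizeFactorSet:
    """Per-sample scaling constants from one normalization method.

    Median-of-ratios and upper-quartile factors absorb sequencing depth;
    TMM factors are composition-only corrections with geometric mean 1 and
    must be combined with library sizes to give effective depths.
    """

    method: str  # "median-of-ratios" | "TMM" | "upper-quartile"
    factors: dict[str, float]

    def __post_init__(self) -> None:
        bad = [s for s, f in self.factors.items() if not f > 0]
        if bad:
            raise ValueError(f"non-positive size factor for samples {bad}")

    def as_array(self, sample_ids: list[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.factors]
        if missing:
            raise ValueError(f"no size factor for samples {missing}")
        return np.array([self.factors[s] for s in sample_ids], dtype=float)


@dataclass
class Dendrogram:
    """Result of agglomerative average-linkage clustering.

    Leaves are numbered 0..n-1 in input order; the i-th merge creates
    internal node n+i.  ``merges`` rows are (left, right, height, size)
    with height the average inter-cluster euclidean distance at the merge.
    """

    leaf_labels: list[str]
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]


@dataclass
class ConsensusResult:
    """Intersection of the significant sets of the two DE backends."""

    contrast: str
    alpha: float
    significant_a: set[str]
    significant_b: set[str]
    consensus: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.consensus = self.significant_a & self.significant_b
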