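"""Table I/O, configuration and the end-to-end screening report.

Interchange formats are plain text: CSV/TSV with explicit headers for
tables, JSON for reports and ground truth, YAML for configuration, Newick
for dendrograms.  Readers validate against the domain invariants (schema,
sign, label codes, duplicate ids) and report offending rows; numbers in the
report are rounded to six significant digits so regeneration under a fixed
seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .phenotyping import (
    FetusRecord,
    LOSLabelSet,
    classify_los,
    los_prevalence,
    sex_ratio_test,
)
from .fetometry import UltrasoundExam, fetometry_report, FIXED_THRESHOLD
from .leukotranscript import (
    CountMatrix,
    SampleMeta,
    size_factors_mor,
    normalize,
    hierarchical_cluster,
    to_newick,
    nb_lrt,
    consensus,
    select_reference_genes,
)
from .leukotranscript.containers import meta_frame
from .qpcr import ddct_fold

MORPHOMETRY_COLUMNS = ["fetus_id", "dam_id", "group", "sex", "day", "weight_g", "twin"]
ULTRASOUND_COLUMNS = ["fetus_id", "day", "AH", "AD", "TD", "TH", "CRL", "HL", "BPD"]
SAMPLEMETA_COLUMNS = [
    "sample_id", "dam_id", "day", "group", "n_fetuses", "total_fetal_mass", "extreme",
]


class ValidationError(ValueError):
    """Schema or invariant violation in an input table."""


# ---------------------------------------------------------------------------
# morphometry

def write_morphometry_csv(records: list[FetusRecord], path: str | Path) -> None:
    measurement_names = sorted({m for r in records for m in r.collection_measurements})
    rows = []
    for r in records:
        row = {
            "fetus_id": r.fetus_id, "dam_id": r.dam_id, "group": r.group,
            "sex": r.sex, "day": r.day, "weight_g": r.weight, "twin": r.twin,
        }
        for m in measurement_names:
            row[m] = r.collection_measurements.get(m, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_morphometry_csv(path: str | Path) -> list[FetusRecord]:
    df = pd.read_csv(path)
    _require_columns(df, MORPHOMETRY_COLUMNS, path)
    _require_unique(df, "fetus_id", path)
    extra = [c for c in df.columns if c not in MORPHOMETRY_COLUMNS]
    records = []
    for i, row in df.iterrows():
        try:
            measurements = {
                m: float(row[m]) for m in extra if pd.notna(row[m]) and row[m] != ""
            }
            records.append(
                FetusRecord(
                    fetus_id=str(row["fetus_id"]), dam_id=str(row["dam_id"]),
                    group=str(row["group"]), sex=str(row["sex"]),
                    day=int(row["day"]), weight=float(row["weight_g"]),
                    twin=_parse_bool(row["twin"]),
                    collection_measurements=measurements,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}, row {i + 2}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# ultrasound

def write_ultrasound_csv(exams: list[UltrasoundExam], path: str | Path) -> None:
    pd.DataFrame(
        [
            {c: getattr(e, c) for c in ULTRASOUND_COLUMNS}
            for e in exams
        ]
    ).to_csv(path, index=False)


def read_ultrasound_csv(path: str | Path) -> list[UltrasoundExam]:
    df = pd.read_csv(path)
    _require_columns(df, ULTRASOUND_COLUMNS, path)
    _require_unique(df, "fetus_id", path)
    exams = []
    for i, row in df.iterrows():
        values = {c: float(row[c]) for c in ULTRASOUND_COLUMNS[2:]}
        bad = [c for c, v in values.items() if not v > 0]
        if bad:
            raise ValidationError(
                f"{path}, row {i + 2}: non-positive measurement {bad[0]!r}"
            )
        exams.append(
            UltrasoundExam(fetus_id=str(row["fetus_id"]), day=int(row["day"]), **values)
        )
    return exams


# ---------------------------------------------------------------------------
# counts and sample metadata

def write_counts_tsv(counts: CountMatrix, path: str | Path) -> None:
    counts.to_frame().rename_axis("gene").to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate gene or sample ids")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric count entries")
    if np.any(values < 0):
        g, s = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{path}: negative count for gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if np.any(values != np.rint(values)):
        g, s = np.argwhere(values != np.rint(values))[0]
        raise ValidationError(
            f"{path}: non-integer count for gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                       values.astype(np.int64))


def write_samplemeta_csv(samples: list[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(s, c) for c in SAMPLEMETA_COLUMNS} for s in samples]
    ).to_csv(path, index=False)


def read_samplemeta_csv(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path)
    _require_columns(df, SAMPLEMETA_COLUMNS, path)
    _require_unique(df, "sample_id", path)
    samples = []
    for i, row in df.iterrows():
        group = str(row["group"])
        if group not in ("Control-AI", "IVP-Normal", "IVP-LOS"):
            raise ValidationError(f"{path}, row {i + 2}: unknown group code {group!r}")
        try:
            samples.append(
                SampleMeta(
                    sample_id=str(row["sample_id"]), dam_id=str(row["dam_id"]),
                    day=int(row["day"]), group=group,
                    n_fetuses=int(row["n_fetuses"]),
                    total_fetal_mass=float(row["total_fetal_mass"]),
                    extreme=_parse_bool(row["extreme"]),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}, row {i + 2}: {exc}") from exc
    return samples


# ---------------------------------------------------------------------------
# CT tables

def write_ct_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "gene", "CT", "role"], path)
    bad_role = df.loc[~df["role"].isin(["target", "reference"])]
    if len(bad_role):
        raise ValidationError(
            f"{path}, row {bad_role.index[0] + 2}: unknown role {bad_role['role'].iloc[0]!r}"
        )
    if np.any(df["CT"] <= 0):
        i = int(np.argmax((df["CT"] <= 0).to_numpy()))
        raise ValidationError(f"{path}, row {i + 2}: non-positive CT")
    return df


def write_truth_json(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration

@dataclass
class PipelineConfig:
    """Paths and tuning parameters of the end-to-end screen.

    Transcriptome and qPCR stages run only when their input paths are set;
    a morphometry-only configuration is valid.
    """

    morphometry_csv: str = ""
    ultrasound_csv: str = ""
    counts_tsv: str = ""
    samplemeta_csv: str = ""
    ct_csv: str = ""
    out_dir: str = "results"
    q: float = 0.97  # percentile defining overgrowth
    threshold_mode: str = "control-max"  # or "fixed:100"
    alpha: float = 0.05  # DE significance level on adjusted p
    cv_max: float = 0.10  # reference-gene stability bound
    log_transform_clustering: bool = False
    dispersion_prior_weight_a: float = 10.0
    dispersion_prior_weight_b: float = 0.0
    qpcr_targets: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.q < 1:
            raise ValidationError(f"q={self.q} outside (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha={self.alpha} outside (0, 1)")
        if self.threshold_mode != "control-max" and not self.threshold_mode.startswith("fixed:"):
            raise ValidationError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not self.morphometry_csv:
            raise ValidationError("morphometry_csv is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sig6(x):
    """Round floats to 6 significant digits for reproducible reports."""
    if isinstance(x, float):
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _sig6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_sig6(v) for v in x]
    return x


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage and write a JSON report.

    Stage order mirrors the analysis: classification, fetometry screen,
    sex-ratio tests, clustering, differential expression with dual-backend
    consensus, reference-gene selection, and delta-delta-CT quantification.
    Any stage failure aborts with the stage name and cause.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        report["stages"].append(name)
        return result

    # -- classification ----------------------------------------------------
    fetuses = stage("read_morphometry", lambda: read_morphometry_csv(config.morphometry_csv))
    labels = stage("classify", lambda: classify_los(fetuses, q=config.q))
    report["thresholds_g"] = labels.thresholds
    report["labels"] = labels.labels
    report["los_prevalence"] = los_prevalence(labels)
    pd.Series(labels.labels, name="label").rename_axis("fetus_id").to_csv(
        out_dir / "labels.csv"
    )

    # -- sex ratio ----------------------------------------------------------
    def sex_ratios():
        out = {}
        for grp in ("AI", "IVP"):
            sub = [f for f in fetuses if f.group == grp]
            if sub:
                n_f = sum(1 for f in sub if f.sex == "F")
                out[grp] = {
                    "n_female": n_f, "n_total": len(sub),
                    "p_value": sex_ratio_test(n_f, len(sub)).p_value,
                }
        return out

    report["sex_ratio"] = stage("sexratio", sex_ratios)

    # -- fetometry ----------------------------------------------------------
    if config.ultrasound_csv:
        exams = stage("read_ultrasound", lambda: read_ultrasound_csv(config.ultrasound_csv))
        fixed = (
            float(config.threshold_mode.split(":", 1)[1])
            if config.threshold_mode.startswith("fixed:")
            else None
        )
        table, correlations = stage(
            "fetometry", lambda: fetometry_report(exams, fetuses, labels, threshold=fixed)
        )
        table.to_csv(out_dir / "fetometry.csv", index=False)
        report["fetometry"] = {
            "threshold": float(table["threshold"].iloc[0]) if len(table) else None,
            "n_flagged": int(table["flagged"].sum()),
            "flagged": sorted(table.loc[table["flagged"], "fetus_id"]),
            "correlations": [
                {"pair": list(c.pair), "r": c.r, "p": c.p, "n": c.n} for c in correlations
            ],
        }

    # -- transcriptome -------------------------------------------------------
    if config.counts_tsv and config.samplemeta_csv:
        counts = stage("read_counts", lambda: read_counts_tsv(config.counts_tsv))
        samples = stage("read_samplemeta", lambda: read_samplemeta_csv(config.samplemeta_csv))
        meta = meta_frame(samples)
        if set(meta.index) != set(counts.sample_ids):
            raise RuntimeError(
                "stage 'read_samplemeta' failed: metadata samples do not match count columns"
            )

        sf = stage("size_factors", lambda: size_factors_mor(counts))
        pd.Series(sf.factors, name="size_factor").rename_axis("sample_id").to_csv(
            out_dir / "size_factors.csv"
        )
        report["size_factors"] = sf.factors

        norm = normalize(counts, sf, log2=config.log_transform_clustering)
        dend = stage("cluster", lambda: hierarchical_cluster(norm, counts.sample_ids))
        newick_path = out_dir / "dendrogram.nwk"
        newick_path.write_text(to_newick(dend) + "\n")
        report["dendrogram_newick"] = str(newick_path)

        def run_de():
            de_out = {}
            contrasts = [("extreme-vs-rest", "extreme", None)]
            groups = sorted(meta["group"].unique())
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    contrasts.append(
                        (f"{groups[a]}-vs-{groups[b]}", "group",
                         meta["group"].isin([groups[a], groups[b]]))
                    )
            if meta["n_fetuses"].nunique() > 1:
                contrasts.append(("twins-vs-singletons", "n_fetuses", None))
            for name, factor, mask in contrasts:
                sub_ids = list(meta.index[mask]) if mask is not None else counts.sample_ids
                idx = [counts.sample_ids.index(s) for s in sub_ids]
                sub = CountMatrix(counts.gene_ids, sub_ids, counts.counts[:, idx])
                sub_meta = meta.loc[sub_ids]
                if sub_meta[factor].nunique() < 2:
                    continue
                ta = nb_lrt(sub, sub_meta, [factor], [], backend="A",
                            dispersion_prior_weight=config.dispersion_prior_weight_a)
                tb = nb_lrt(sub, sub_meta, [factor], [], backend="B",
                            dispersion_prior_weight=config.dispersion_prior_weight_b)
                cons = consensus(ta, tb, alpha=config.alpha, contrast=name)
                ta.to_csv(out_dir / f"de_{name}_A.tsv", sep="\t")
                tb.to_csv(out_dir / f"de_{name}_B.tsv", sep="\t")
                de_out[name] = {
                    "n_significant_A": len(cons.significant_a),
                    "n_significant_B": len(cons.significant_b),
                    "consensus": sorted(cons.consensus),
                }
                if name == "extreme-vs-rest":
                    norm_df = pd.DataFrame(
                        normalize(counts, sf), index=counts.gene_ids,
                        columns=counts.sample_ids,
                    )
                    report["reference_genes"] = select_reference_genes(
                        ta, tb, norm_df, cv_max=config.cv_max
                    )
            return de_out

        report["differential_expression"] = stage("de", run_de)

    # -- qPCR ----------------------------------------------------------------
    if config.ct_csv and config.samplemeta_csv:
        ct = stage("read_ct", lambda: read_ct_csv(config.ct_csv))
        samples = read_samplemeta_csv(config.samplemeta_csv)
        in_table = set(ct["sample_id"])
        extreme_ids = {s.sample_id for s in samples if s.extreme} & in_table
        baseline = sorted(in_table - extreme_ids)
        targets = config.qpcr_targets or sorted(
            ct.loc[ct["role"] == "target", "gene"].unique()
        )
        qpcr_out = {}
        for target in targets:
            res = stage(
                f"qpcr:{target}",
                lambda t=target: ddct_fold(ct, t, baseline=baseline, test=extreme_ids),
            )
            res.folds.rename_axis("sample_id").to_csv(out_dir / f"qpcr_{target}.csv")
            qpcr_out[target] = {s: float(res.folds[s]) for s in sorted(extreme_ids & set(res.folds.index))}
        report["qpcr_folds"] = qpcr_out

    report = _sig6(report)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _require_unique(df: pd.DataFrame, column: str, path) -> None:
    dup = df[column][df[column].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate {column} {dup.iloc[0]!r}")


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")
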