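"""Core data containers and delimited-text I/O shared by every pipeline stage.

The pipeline moves four kinds of tables around:

* an expression matrix — genes in rows, samples in columns, per-gene z-scores
  across samples (the ``exp_cg`` of the polygenic score);
* a long-format drug-response table — one ln(IC50) or AUC value per
  (drug, sample) pair, with the convention that *larger value = more
  resistant* for both metrics;
* a sample annotation mapping cell lines to a lineage (cancer type);
* clinical follow-up records (time, event, optional age/stage/grade).

All files are tab-separated UTF-8 text with a header row, the dialect used by
the public pharmacogenomic portals once exported to TSV.  Missing expression
values are preserved as missing (never imputed); downstream correlations use
pairwise-complete samples.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens interpreted as a missing value in any numeric field
NA_TOKENS = frozenset({"", "NA", "N/A", "NaN", "nan", "null", "NULL"})

VALID_METRICS = ("LN_IC50", "AUC")


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifier(s): {dup[:5]}")


def zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, sd 1 (ddof=1) over non-missing entries.

    Rows with zero variance (or fewer than two non-missing values) become
    all-zero, with a warning; the missingness pattern is preserved.
    """
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    flat = (sd == 0) | sd.isna()
    out = df.sub(mean, axis=0).div(sd.where(~flat), axis=0)
    if flat.any():
        out.loc[flat] = df.loc[flat] * 0.0  # 0*NaN keeps NaN where missing
        logger.warning(
            "z-scoring: %d zero-variance gene row(s) set to all-zero", int(flat.sum())
        )
    return out


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (optionally z-scored) expression values."""

    data: pd.DataFrame
    zscored: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def zscore(self) -> "ExpressionMatrix":
        """Return a per-gene standardized copy. Idempotent on z-scored input."""
        return ExpressionMatrix(zscore_rows(self.data), zscored=True)

    def validate(self) -> None:
        """Check the z-score invariant on every non-flat gene row."""
        if not self.zscored:
            return
        mean = self.data.mean(axis=1)
        sd = self.data.std(axis=1, ddof=1)
        nonflat = sd > 0
        if nonflat.any():
            if (mean[nonflat].abs() > 1e-8).any():
                raise ValueError("z-scored matrix has a gene row with mean far from 0")
            if ((sd[nonflat] - 1.0).abs() > 1e-6).any():
                raise ValueError("z-scored matrix has a gene row with sd far from 1")

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id")


def read_expression(path, zscore_on_load: bool = False) -> ExpressionMatrix:
    """Read a genes-in-rows TSV expression matrix.

    The first column holds gene ids, the header row sample ids.  Non-numeric
    cells are rejected with their (gene, sample) coordinates; NA tokens become
    missing values.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    sample_ids = [h.strip() for h in header[1:]]
    _check_unique(sample_ids, "sample")
    gene_ids, values = [], []
    for r, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        gene = row[0].strip()
        gene_ids.append(gene)
        parsed = []
        for c, tok in enumerate(row[1:]):
            tok = tok.strip()
            if tok in NA_TOKENS:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(tok))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {tok!r} at gene {gene!r}, "
                    f"sample {sample_ids[c] if c < len(sample_ids) else c!r} (line {r})"
                ) from None
        values.append(parsed)
    _check_unique(gene_ids, "gene")
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids, dtype=float)
    if zscore_on_load:
        return ExpressionMatrix(zscore_rows(df), zscored=True)
    return ExpressionMatrix(df, zscored=False)


@dataclass
class DrugResponseTable:
    """Long-format drug response records; one row per (drug, sample)."""

    data: pd.DataFrame  # columns: drug_id, sample_id, value
    metric: str = "LN_IC50"

    def __post_init__(self) -> None:
        if self.metric not in VALID_METRICS:
            raise ValueError(f"metric must be one of {VALID_METRICS}, got {self.metric!r}")
        required = ["drug_id", "sample_id", "value"]
        if list(self.data.columns[:3]) != required:
            self.data = self.data.rename(
                columns=dict(zip(self.data.columns[:3], required))
            )
        dup = self.data.duplicated(subset=["drug_id", "sample_id"])
        if dup.any():
            pair = self.data.loc[dup.idxmax(), ["drug_id", "sample_id"]].tolist()
            raise ValueError(f"duplicate (drug, sample) record: {tuple(pair)}")
        self.data = self.data.assign(value=self.data["value"].astype(float))

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.data["drug_id"].unique())

    def response_vector(self, drug_id: str) -> pd.Series:
        sub = self.data[self.data["drug_id"] == drug_id]
        if sub.empty:
            raise KeyError(f"drug {drug_id!r} not present in response table")
        return sub.set_index("sample_id")["value"]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def read_drug_response(path, metric: str = "LN_IC50") -> DrugResponseTable:
    """Read a long-format (drug, sample, value) TSV; rows with a missing value
    token are skipped and counted."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (drug, sample, value)")
    raw = raw.iloc[:, :3]
    raw.columns = ["drug_id", "sample_id", "value"]
    missing = raw["value"].str.strip().isin(NA_TOKENS)
    if missing.any():
        logger.warning("read_drug_response: skipped %d row(s) with missing value", int(missing.sum()))
    kept = raw[~missing].copy()
    kept["value"] = kept["value"].astype(float)
    return DrugResponseTable(kept.reset_index(drop=True), metric=metric)


@dataclass
class SampleAnnotation:
    """sample_id -> lineage (cancer type) and optional cohort tag."""

    data: pd.DataFrame  # index sample_id, columns lineage[, cohort]

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        if "lineage" not in self.data.columns:
            raise ValueError("annotation requires a 'lineage' column")
        if (self.data["lineage"].astype(str).str.len() == 0).any():
            raise ValueError("empty lineage label")

    def samples_in_lineage(self, lineage: str) -> list[str]:
        return list(self.data.index[self.data["lineage"] == lineage])

    @property
    def lineages(self) -> list[str]:
        return sorted(self.data["lineage"].unique())

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation(path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleAnnotation(df)


def read_clinical(path) -> pd.DataFrame:
    """Read clinical follow-up: sample_id, time (months), event (0/1) and
    optional age/stage/grade covariates. Returns a sample-indexed frame."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(NA_TOKENS),
                     float_precision="round_trip")
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: clinical table requires a {col!r} column")
    _check_unique(df.index, "sample")
    if (df["time"] <= 0).any():
        raise ValueError("clinical table has non-positive follow-up time")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as TSV with a stable column order and header.

    Floats are written with Python's shortest round-tripping repr, so
    ``read_table(write_table(df))`` reproduces values bit-identically.
    """
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=list(NA_TOKENS),
                       keep_default_na=False, float_precision="round_trip")
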