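"""Readers and writers for the interchange formats shared by every stage.

All tabular interchange is TSV (UTF-8, ``.`` decimal separator, ``NA`` for
unknown categorical values), matching GEO series-matrix conventions. Gene sets
use the GMT dialect (name TAB description TAB member...). Result reports are
JSON, written with sorted keys so identical analyses serialise byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

RNASEQ_LIKE = "rnaseq-like"
MICROARRAY_LIKE = "microarray-like"

#: Required columns of a clinical table, in canonical order.
CLINICAL_COLUMNS = (
    "patient_id",
    "os_months",
    "event",
    "age",
    "gender",
    "t_stage",
    "n_stage",
    "m_stage",
    "hpv",
    "site",
)

#: Optional clinical columns preserved when present.
CLINICAL_OPTIONAL = ("grade",)

NA_TOKEN = "NA"


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    ``values`` is a pandas DataFrame indexed by gene ID with sample IDs as
    columns; ``platform`` tags the technology family the units come from
    (``rnaseq-like`` units are comparable across cohorts, ``microarray-like``
    units are cohort-internal only).
    """

    values: pd.DataFrame
    platform: str = RNASEQ_LIKE

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate gene ID {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r}")
        arr = v.to_numpy(dtype=float, copy=False)
        if arr.size and not np.all(np.isfinite(arr)):
            gene = v.index[np.where(~np.isfinite(arr))[0][0]]
            raise FormatError(f"non-finite expression value in gene {gene!r}")
        if arr.size and arr.min() < 0:
            gene = v.index[np.where((arr < 0).any(axis=1))[0][0]]
            raise FormatError(f"negative expression value in gene {gene!r}")
        if self.platform not in (RNASEQ_LIKE, MICROARRAY_LIKE):
            raise InputError(f"unknown platform tag {self.platform!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def gene(self, gene_id: str) -> np.ndarray:
        from .errors import GeneLookupError

        if gene_id not in self.values.index:
            raise GeneLookupError(f"gene {gene_id!r} not in matrix")
        return self.values.loc[gene_id].to_numpy(dtype=float)


@dataclass
class NormalTissuePanel:
    """Normal-tissue expression panel with a tissue label per sample.

    ``germline_tissues`` are the tissues excluded from the somatic-silence
    requirement (testis, ovary, placenta in the default study design).
    """

    expression: ExpressionMatrix
    tissue_of_sample: pd.Series  # sample_id -> tissue name
    germline_tissues: frozenset = frozenset()

    def __post_init__(self) -> None:
        missing = [s for s in self.expression.sample_ids if s not in self.tissue_of_sample.index]
        if missing:
            raise InputError(f"samples without tissue label: {missing[:5]}")
        self.tissue_of_sample = self.tissue_of_sample.loc[self.expression.sample_ids]
        self.germline_tissues = frozenset(self.germline_tissues)

    @property
    def tissues(self) -> list[str]:
        return sorted(set(self.tissue_of_sample))


@dataclass
class TumorCohort:
    """Tumour expression matrix aligned with its clinical table."""

    expression: ExpressionMatrix
    clinical: pd.DataFrame  # indexed by patient_id

    def __post_init__(self) -> None:
        if list(self.expression.sample_ids) != list(self.clinical.index):
            if set(self.expression.sample_ids) != set(self.clinical.index):
                raise InputError("expression samples and clinical patients do not match")
            self.clinical = self.clinical.loc[self.expression.sample_ids]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clinical.index)

    @property
    def time(self) -> np.ndarray:
        return self.clinical["os_months"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.clinical["event"].to_numpy(dtype=int)


@dataclass(frozen=True)
class GeneSet:
    """Named gene set as exchanged in GMT files."""

    name: str
    description: str
    genes: tuple

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")

    @property
    def members(self) -> frozenset:
        return frozenset(self.genes)


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_matrix(path, platform: str = RNASEQ_LIKE) -> ExpressionMatrix:
    """Read a genes x samples TSV (header of sample IDs, gene-ID first column).

    Raises :class:`FormatError` naming the offending line for ragged rows,
    unparseable or negative values, and duplicate IDs.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
        if not header:
            raise FormatError(f"{path.name}: empty file")
        samples = header.split("\t")[1:]
        ncol = len(samples)
        genes: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != ncol + 1:
                raise FormatError(
                    f"{path.name}, line {lineno}: expected {ncol + 1} fields, found {len(parts)}"
                )
            try:
                row = np.asarray(parts[1:], dtype=float)
            except ValueError as exc:
                raise FormatError(f"{path.name}, line {lineno}: unparseable value ({exc})") from exc
            if not np.all(np.isfinite(row)):
                raise FormatError(f"{path.name}, line {lineno}: non-finite value")
            if row.size and row.min() < 0:
                raise FormatError(f"{path.name}, line {lineno}: negative expression value")
            genes.append(parts[0])
            rows.append(row)
    values = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, ncol)), index=genes, columns=samples
    )
    return ExpressionMatrix(values, platform=platform)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# tissue labels

def read_tissue_labels(path) -> tuple[pd.Series, frozenset]:
    """Read a sample->tissue TSV with columns sample_id, tissue, germline (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "tissue", "germline"):
        if col not in df.columns:
            raise FormatError(f"tissue table missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample ID {dup!r} in tissue table")
    labels = pd.Series(df["tissue"].to_numpy(), index=df["sample_id"].to_numpy())
    germ = frozenset(df.loc[df["germline"].astype(int) == 1, "tissue"])
    return labels, germ


def write_tissue_labels(labels: pd.Series, germline: Iterable[str], path) -> None:
    germline = set(germline)
    df = pd.DataFrame(
        {
            "sample_id": labels.index,
            "tissue": labels.to_numpy(),
            "germline": [int(t in germline) for t in labels.to_numpy()],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# clinical tables

_HPV_LEVELS = {"positive", "negative", "unknown"}
_SITE_LEVELS = {"TBOT", "other", "unknown"}


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a clinical table (patient_id index on return)."""
    df = df.copy()
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"clinical table missing required column {col!r}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise FormatError(f"duplicate patient ID {dup!r}")
    df["os_months"] = pd.to_numeric(df["os_months"], errors="raise")
    if (df["os_months"] <= 0).any() or not np.isfinite(df["os_months"]).all():
        bad = df.loc[~(df["os_months"] > 0), "patient_id"].iloc[0]
        raise FormatError(f"os_months must be positive and finite (patient {bad!r})")
    df["event"] = pd.to_numeric(df["event"], errors="raise")
    if not df["event"].isin([0, 1]).all():
        bad = df.loc[~df["event"].isin([0, 1]), "patient_id"].iloc[0]
        raise FormatError(f"event must be 0 or 1 (patient {bad!r})")
    df["event"] = df["event"].astype(int)
    df["age"] = pd.to_numeric(df["age"].replace(NA_TOKEN, np.nan), errors="raise")
    for col in ("t_stage", "n_stage", "m_stage"):
        df[col] = pd.to_numeric(df[col].replace(NA_TOKEN, np.nan), errors="raise").astype("Int64")
    for col, levels in (("hpv", _HPV_LEVELS), ("site", _SITE_LEVELS)):
        df[col] = df[col].astype(str).replace(NA_TOKEN, "unknown")
        bad = ~df[col].isin(levels)
        if bad.any():
            raise FormatError(
                f"{col} value {df.loc[bad, col].iloc[0]!r} not in {sorted(levels)}"
            )
    if "grade" in df.columns:
        df["grade"] = df["grade"].astype(str).replace(NA_TOKEN, "unknown")
    keep = list(CLINICAL_COLUMNS) + [c for c in CLINICAL_OPTIONAL if c in df.columns]
    return df[keep].set_index("patient_id")


def read_clinical_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_clinical(df)


def write_clinical_table(clinical: pd.DataFrame, path) -> None:
    df = clinical.reset_index()
    if df.columns[0] != "patient_id":
        df = df.rename(columns={df.columns[0]: "patient_id"})
    for col in ("t_stage", "n_stage", "m_stage"):
        df[col] = df[col].astype(object).where(pd.notna(df[col]), NA_TOKEN)
    df = df.replace("unknown", NA_TOKEN)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# IHC tables

IHC_COLUMNS = ("patient_id", "marker", "intensity", "percent_positive")


def read_ihc_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in IHC_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"IHC table missing required column {col!r}")
    df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
    df["percent_positive"] = pd.to_numeric(df["percent_positive"], errors="raise")
    if not df["intensity"].isin([0, 1, 2, 3]).all():
        raise FormatError("IHC intensity must be an integer in 0..3")
    df["intensity"] = df["intensity"].astype(int)
    if ((df["percent_positive"] < 0) | (df["percent_positive"] > 100)).any():
        raise FormatError("IHC percent_positive must lie in [0, 100]")
    if df.duplicated(subset=["patient_id", "marker"]).any():
        pair = df.loc[df.duplicated(subset=["patient_id", "marker"]), ["patient_id", "marker"]]
        raise FormatError(f"duplicate IHC record for {tuple(pair.iloc[0])}")
    return df[list(IHC_COLUMNS)]


def write_ihc_table(table: pd.DataFrame, path) -> None:
    table[list(IHC_COLUMNS)].to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, members = parts[0], parts[1], parts[2:]
            members = [m for m in members if m]
            seen: dict[str, None] = {}
            for m in members:
                seen.setdefault(m, None)
            if not seen:
                raise FormatError(f"GMT line {lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, description=desc, genes=tuple(seen)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# JSON reports

def write_json_report(obj, path) -> None:
    """Serialise a report dict deterministically (sorted keys, no timestamps)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
        fh.write("\n")


def read_json_report(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
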