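"""Readers and writers for the pipeline's tabular formats.

Matrices (beta values, detection p-values, counts) are TSV with a leading
``probe_id`` / ``gene_id`` column and one column per sample; missing values
are empty cells, never ``.``.  The sample sheet and probe annotation are CSV
with fixed required headers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SHEET_COLUMNS = [
    "sample_id",
    "subject_id",
    "session",
    "timepoint",
    "batch",
    "group",
    "monocyte_proportion",
]

ANNOTATION_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "feature_class",
    "gene_symbol",
    "mQTL",
    "circadian_TSS",
]

FEATURE_CLASSES = ("TSS", "5UTR", "Body", "3UTR", "undefined")


def read_matrix(path: str | Path, index_name: str = "probe_id") -> pd.DataFrame:
    """Read a feature x sample TSV matrix into a float DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[""], keep_default_na=False)
    df.index.name = index_name
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {index_name}s in {path}: {dupes[:5]}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    validate_sample_sheet(sheet)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    mono = sheet["monocyte_proportion"].astype(float)
    if ((mono < 0) | (mono > 1)).any():
        raise ValueError("monocyte_proportion outside [0, 1]")
    counts = sheet.groupby("subject_id").size()
    if (counts > 8).any():
        bad = counts[counts > 8].index.tolist()
        raise ValueError(f"subjects with more than 8 samples: {bad}")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    bad = set(ann["feature_class"]) - set(FEATURE_CLASSES)
    if bad:
        raise ValueError(f"unknown feature classes: {sorted(bad)}")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, index=False)


def check_alignment(matrix: pd.DataFrame, sheet: pd.DataFrame) -> None:
    """Require matrix columns and sample-sheet ids to match as sets."""
    mat = set(matrix.columns)
    sh = set(sheet["sample_id"])
    if mat != sh:
        only_mat = sorted(mat - sh)[:5]
        only_sheet = sorted(sh - mat)[:5]
        raise ValueError(
            f"matrix/sheet sample mismatch; matrix-only {only_mat}, sheet-only {only_sheet}"
        )


def read_probe_sets(path: str | Path) -> dict[str, list[str]]:
    """Read a probe-set CSV with columns (set_name, probe_id)."""
    df = pd.read_csv(path)
    for col in ("set_name", "probe_id"):
        if col not in df.columns:
            raise ValueError(f"probe-set file missing column {col!r}")
    return {
        name: grp["probe_id"].astype(str).unique().tolist()
        for name, grp in df.groupby("set_name", sort=False)
    }


def write_probe_sets(sets: dict[str, list[str]], path: str | Path) -> None:
    rows = [(name, pid) for name, pids in sets.items() for pid in pids]
    pd.DataFrame(rows, columns=["set_name", "probe_id"]).to_csv(path, index=False)


def read_icc_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "scenario", "icc21", "icc2k", "adjusted", "converged"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ICC table missing columns: {sorted(missing)}")
    return df


def write_icc_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
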