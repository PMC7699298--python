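"""Readers and writers for the on-disk formats.

Native dialect: tab-separated tables with '#'-prefixed header comments
(ignored on read, used on write to record tool version and parameters);
gene sets in GMT (set name, description, members, tab-separated); summaries
in JSON.  Parse errors name the file and, where possible, the line.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrich import GeneSetCollection
from .meta import StudySummary
from .pool import PoolCountTable
from .qpcr import CtTable
from .screen import ExpressionStudy

__all__ = [
    "ParseError",
    "read_count_table",
    "read_design",
    "read_ct_table",
    "read_expression",
    "read_gmt",
    "read_study_summaries",
    "write_tsv",
    "write_gmt",
    "write_count_table",
    "write_design",
    "write_expression",
    "write_ct_table",
    "write_study_summaries",
]


class ParseError(ValueError):
    def __init__(self, path, message, line: int | None = None):
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")


def _read_commented_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(path, "file does not exist")
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(path, f"malformed table: {exc}") from exc


def _check_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ParseError(path, f"non-numeric values in column(s) {bad}")
    return df


def write_tsv(path, df: pd.DataFrame, params: dict | None = None, index: bool = True) -> None:
    """Write a table with a '#'-comment provenance header."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# mirtrend {__version__}\n")
        for k, v in (params or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------------------
# count tables + designs
# ---------------------------------------------------------------------------

def read_design(path) -> pd.Series:
    """Two-column design: sample_id, group."""
    df = _read_commented_tsv(path)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ParseError(path, f"design is missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(path, f"sample {dup!r} assigned more than once")
    return df.set_index("sample_id")["group"]


def read_count_table(counts_path, design_path) -> PoolCountTable:
    """Count matrix (first column = feature id, header = sample ids) plus design."""
    df = _read_commented_tsv(counts_path, index_col=0)
    if df.index.duplicated().any():
        pos = int(np.nonzero(df.index.duplicated())[0][0])
        dup = df.index[pos]
        raise ParseError(counts_path, f"duplicate feature id {dup!r}", line=pos + 2)
    _check_numeric(df, counts_path)
    groups = read_design(design_path)
    missing = [s for s in df.columns if s not in groups.index]
    if missing:
        raise ParseError(design_path, f"samples missing from the design: {missing}")
    return PoolCountTable(counts=df, groups=groups)


def write_count_table(counts_path, design_path, table: PoolCountTable, params=None) -> None:
    write_tsv(counts_path, table.counts.rename_axis("mirna_id"), params)
    write_design(design_path, table.groups)


def write_design(path, groups: pd.Series) -> None:
    write_tsv(path, groups.rename("group").rename_axis("sample_id").reset_index(), index=False)


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def read_ct_table(path) -> CtTable:
    df = _read_commented_tsv(path)
    try:
        return CtTable(df)
    except ValueError as exc:
        raise ParseError(path, str(exc)) from exc


def write_ct_table(path, table: CtTable, params=None) -> None:
    write_tsv(path, table.data, params, index=False)


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

def read_expression(path, design_path, **study_kwargs) -> ExpressionStudy:
    """Expression matrix plus design (sample_id, context, treatment, replicate)."""
    expr = _read_commented_tsv(path, index_col=0)
    _check_numeric(expr, path)
    design = _read_commented_tsv(design_path)
    for col in ("sample_id", "context", "treatment", "replicate"):
        if col not in design.columns:
            raise ParseError(design_path, f"design is missing column {col!r}")
    design = design.set_index("sample_id")
    missing = [s for s in expr.columns if s not in design.index]
    if missing:
        raise ParseError(design_path, f"samples missing from the design: {missing}")
    try:
        return ExpressionStudy(expression=expr, design=design, **study_kwargs)
    except ValueError as exc:
        raise ParseError(path, str(exc)) from exc


def write_expression(path, design_path, study: ExpressionStudy, params=None) -> None:
    write_tsv(path, study.expression.rename_axis("gene_id"), params)
    write_tsv(design_path, study.design.reset_index(), params, index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    path = Path(path)
    if not path.exists():
        raise ParseError(path, "file does not exist")
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, "GMT line needs name, description and >= 1 member", lineno)
            name, desc, *members = parts
            members = [m for m in members if m]
            if name in sets:
                raise ParseError(path, f"duplicate gene set name {name!r}", lineno)
            if not members:
                raise ParseError(path, f"gene set {name!r} has no members", lineno)
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        raise ParseError(path, "no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=str(path))


def write_gmt(path, collection: GeneSetCollection) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# meta-analysis study summaries
# ---------------------------------------------------------------------------

_STUDY_COLS = ["study", "n_case", "mean_case", "sd_case", "n_control", "mean_control", "sd_control"]


def read_study_summaries(path) -> list[StudySummary]:
    """CSV with columns study, n_case, mean_case, sd_case, n_control,
    mean_control, sd_control."""
    path = Path(path)
    if not path.exists():
        raise ParseError(path, "file does not exist")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _STUDY_COLS if c not in df.columns]
    if missing:
        raise ParseError(path, f"missing column(s) {missing}")
    if df["study"].duplicated().any():
        dup = df.loc[df["study"].duplicated(), "study"].iloc[0]
        raise ParseError(path, f"duplicate study id {dup!r}")
    studies = []
    for i, row in df.iterrows():
        try:
            studies.append(
                StudySummary(
                    study_id=str(row["study"]),
                    n_case=int(row["n_case"]),
                    mean_case=float(row["mean_case"]),
                    sd_case=float(row["sd_case"]),
                    n_control=int(row["n_control"]),
                    mean_control=float(row["mean_control"]),
                    sd_control=float(row["sd_control"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(path, str(exc), line=i + 2) from exc
    return studies


def write_study_summaries(path, studies: Sequence[StudySummary]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                "study": s.study_id,
                "n_case": s.n_case,
                "mean_case": s.mean_case,
                "sd_case": s.sd_case,
                "n_control": s.n_control,
                "mean_control": s.mean_control,
                "sd_control": s.sd_control,
            }
            for s in studies
        ]
    )
    # %.17g keeps float64 round-trips exact
    df.to_csv(path, index=False, float_format="%.17g")


def write_json(path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
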