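"""Readers and writers for the pipeline's tabular formats.

All tables are plain UTF-8 CSV/TSV with a header row and species names in
the first column.  Concentration matrices carry a ``# units:`` comment line
so files are self-describing; numeric payloads round-trip at 12 significant
digits.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SampleMetadataMismatchError, TableFormatError
from .quantify import ConcentrationMatrix, FeatureTable, SampleMeta

__all__ = [
    "read_feature_table",
    "read_metadata",
    "write_concentrations",
    "read_concentrations",
    "write_table",
]

_FLOAT_FMT = "%.12g"


def _sep_for(path: Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_feature_table(path, is_rows: Sequence[str] = ()) -> FeatureTable:
    """Read a peak-area table (species in the first column, samples across).

    Rows listed in ``is_rows``, or whose name contains ``"(IS)"``, are
    flagged as internal standards.
    """
    path = Path(path)
    sep = _sep_for(path)
    # pandas mangles duplicate header names on read; check the raw header
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    columns = [c.strip() for c in header.rstrip("\n").split(sep)][1:]
    dup_cols = {c for c in columns if columns.count(c) > 1}
    if dup_cols:
        raise SampleMetadataMismatchError(
            f"{path}: duplicate sample columns {sorted(dup_cols)}"
        )
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableFormatError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise TableFormatError(f"{path}: duplicate species names {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise SampleMetadataMismatchError(f"{path}: duplicate sample columns {dups}")
    flagged = set(is_rows) | {r for r in df.index if "(IS)" in str(r)}
    flagged &= set(df.index)
    return FeatureTable(areas=df.astype(float), is_rows=sorted(flagged))


def read_metadata(path) -> list[SampleMeta]:
    """Read sample metadata CSV: sample_id, group, tissue, protein_amount
    and optional extract_volume columns."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"sample_id", "group", "protein_amount"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise TableFormatError(f"{path}: duplicate sample IDs")
    metas = []
    for row in df.itertuples():
        metas.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                group=str(row.group),
                tissue=str(getattr(row, "tissue", "SN")),
                protein_amount=float(row.protein_amount),
                extract_volume=float(getattr(row, "extract_volume", 1.0)),
            )
        )
    return metas


def write_concentrations(matrix: ConcentrationMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# units: {matrix.units}\n")
        fh.write(f"# provenance: {matrix.provenance}\n")
        matrix.values.to_csv(fh, float_format=_FLOAT_FMT)


def read_concentrations(path, meta: Sequence[SampleMeta]) -> ConcentrationMatrix:
    path = Path(path)
    units = "ug/ug protein"
    provenance = "supplied"
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith("# units:"):
                units = line.split(":", 1)[1].strip()
            elif line.startswith("# provenance:"):
                provenance = line.split(":", 1)[1].strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, index_col=0)
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in df.columns if s not in by_id]
    if missing:
        raise SampleMetadataMismatchError(f"{path}: samples without metadata {missing}")
    ordered = [by_id[s] for s in df.columns]
    return ConcentrationMatrix(
        values=df.astype(float), meta=ordered, units=units, provenance=provenance
    )


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(Path(path), float_format=_FLOAT_FMT, index_label=index_label)
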