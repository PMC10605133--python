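"""Internal-standard semi-quantification of peak-area feature tables.

Concentrations are estimated per species as

    conc(i, s) = area(i, s) / area(IS_class(i), s)
                 * spike(class(i)) * extract_volume(s) / protein(s)

where the internal standard (IS) is the class-matched deuterated species
spiked into every sample at a known concentration.  The ratio form makes the
result invariant to per-sample global response factors (injection volume,
source drift): multiplying every area in a sample by a constant leaves that
sample's concentrations unchanged.

With the default IS map (every mix component at 100 ug/mL, protein in ug and
extract volume in mL) the output unit is ug lipid per ug protein; psychosine,
quantified against its own deuterated standard (125 ng/mL spike), is reported
in ng per ug protein.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    AllMissingSpeciesError,
    MissingInternalStandardError,
    SampleMetadataMismatchError,
    ZeroInternalStandardAreaError,
)
from .nomenclature import LipidClassInfo, default_registry, parse_lipid_name

logger = logging.getLogger(__name__)

__all__ = [
    "ISEntry",
    "ISMap",
    "SampleMeta",
    "FeatureTable",
    "ConcentrationMatrix",
    "default_is_map",
    "semiquantify",
    "quantify_psy",
    "handle_missing",
]

PSY_CLASS = "PSY"


@dataclass(frozen=True)
class ISEntry:
    species: str
    concentration: float  # spiked concentration in the extract
    unit: str = "ug/mL"


@dataclass
class ISMap:
    """Class code -> internal-standard entry, with an overall dilution factor
    applied to every mix-derived spike concentration."""

    standards: dict[str, ISEntry]
    dilution_factor: float = 1.0

    def entry(self, class_code: str) -> ISEntry:
        try:
            return self.standards[class_code]
        except KeyError:
            raise MissingInternalStandardError(
                f"no internal standard mapped for class {class_code!r}"
            ) from None

    def spike(self, class_code: str) -> float:
        return self.entry(class_code).concentration * self.dilution_factor

    @property
    def is_species(self) -> set[str]:
        return {e.species for e in self.standards.values()}


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: group label, tissue, protein content of the
    extracted aliquot (ug) and extraction volume (mL)."""

    sample_id: str
    group: str
    tissue: str = "SN"
    protein_amount: float = 100.0
    extract_volume: float = 1.0

    def __post_init__(self) -> None:
        if self.protein_amount <= 0:
            raise ValueError(f"{self.sample_id}: protein amount must be > 0")
        if self.extract_volume <= 0:
            raise ValueError(f"{self.sample_id}: extract volume must be > 0")


@dataclass
class FeatureTable:
    """Aligned peak areas: species x samples, with IS rows flagged."""

    areas: pd.DataFrame  # index = species raw names, columns = sample IDs
    is_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.areas.index.has_duplicates:
            dups = self.areas.index[self.areas.index.duplicated()].tolist()
            raise SampleMetadataMismatchError(f"duplicate species rows: {dups}")
        if self.areas.columns.has_duplicates:
            dups = self.areas.columns[self.areas.columns.duplicated()].tolist()
            raise SampleMetadataMismatchError(f"duplicate sample columns: {dups}")
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("peak areas must be non-negative")
        missing = [r for r in self.is_rows if r not in self.areas.index]
        if missing:
            raise SampleMetadataMismatchError(f"IS rows absent from table: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def analyte_rows(self) -> list[str]:
        flagged = set(self.is_rows)
        return [r for r in self.areas.index if r not in flagged]


@dataclass
class ConcentrationMatrix:
    """Species x samples concentrations with sample metadata.

    ``units`` records the scale (default ug lipid / ug protein).
    """

    values: pd.DataFrame
    meta: list[SampleMeta]
    units: str = "ug/ug protein"
    provenance: str = "semi-quantified"

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.meta]
        if list(self.values.columns) != ids:
            raise SampleMetadataMismatchError(
                "concentration columns and metadata sample IDs differ: "
                f"{list(self.values.columns)} vs {ids}"
            )

    def meta_by_id(self) -> dict[str, SampleMeta]:
        return {m.sample_id: m for m in self.meta}

    def groups(self) -> pd.Series:
        return pd.Series(
            {m.sample_id: m.group for m in self.meta}, name="group"
        ).loc[list(self.values.columns)]


def load_is_map(source) -> ISMap:
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    standards = {
        code: ISEntry(
            species=str(e["species"]),
            concentration=float(e["concentration"]),
            unit=str(e.get("unit", "ug/mL")),
        )
        for code, e in doc["standards"].items()
    }
    return ISMap(standards=standards, dilution_factor=float(doc.get("dilution_factor", 1.0)))


_DEFAULT_IS_MAP: ISMap | None = None


def default_is_map() -> ISMap:
    """The bundled 14-standard deuterated mix map plus PSY-d5."""
    global _DEFAULT_IS_MAP
    if _DEFAULT_IS_MAP is None:
        ref = resources.files("lipidkit.data").joinpath("internal_standards.yaml")
        with ref.open() as fh:
            _DEFAULT_IS_MAP = load_is_map(fh)
    return _DEFAULT_IS_MAP


def _check_meta(table: FeatureTable, meta: Sequence[SampleMeta]) -> dict[str, SampleMeta]:
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in table.samples if s not in by_id]
    if missing:
        raise SampleMetadataMismatchError(f"samples without metadata: {missing}")
    return by_id


def semiquantify(
    table: FeatureTable,
    ismap: ISMap | None = None,
    meta: Sequence[SampleMeta] = (),
    registry: Mapping[str, LipidClassInfo] | None = None,
    skip_unknown: bool = False,
) -> ConcentrationMatrix:
    """Convert peak areas to concentrations via class-matched standards.

    IS rows are consumed, not emitted.  A zero IS area in any sample is an
    acquisition failure and raises :class:`ZeroInternalStandardAreaError`
    rather than being imputed.  Unknown class tokens raise unless
    ``skip_unknown`` (skipped species are logged).
    """
    if ismap is None:
        ismap = default_is_map()
    if registry is None:
        registry = default_registry()
    by_id = _check_meta(table, meta)
    samples = table.samples

    rows = {}
    for raw in table.analyte_rows:
        try:
            species = parse_lipid_name(raw, registry)
        except Exception:
            if skip_unknown:
                logger.warning("skipping unparseable species %r", raw)
                continue
            raise
        if species.class_code == PSY_CLASS:
            continue  # psychosine has its own targeted path
        entry = ismap.entry(species.class_code)
        if entry.species not in table.areas.index:
            raise MissingInternalStandardError(
                f"IS row {entry.species!r} (class {species.class_code}) missing"
            )
        is_area = table.areas.loc[entry.species]
        zero = is_area[is_area <= 0]
        if len(zero):
            raise ZeroInternalStandardAreaError(
                f"IS {entry.species!r} has zero area in sample(s) "
                f"{list(zero.index)}; affected samples are invalid"
            )
        spike = ismap.spike(species.class_code)
        conc = table.areas.loc[raw] / is_area * spike
        rows[raw] = conc

    values = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=samples)
    values = values.reindex(columns=samples)
    for s in samples:
        m = by_id[s]
        values[s] = values[s] * m.extract_volume / m.protein_amount
    ordered_meta = [by_id[s] for s in samples]
    return ConcentrationMatrix(values=values, meta=ordered_meta)


def quantify_psy(
    table: FeatureTable,
    ismap: ISMap | None = None,
    meta: Sequence[SampleMeta] = (),
    psy_row: str = "PSY 18:1;O2",
) -> pd.Series:
    """Targeted psychosine quantification against its deuterated standard.

    Returns a per-sample series in ng per ug protein (with the default
    125 ng/mL spike).  A zero psychosine area is a valid zero concentration;
    a zero standard area is an error.
    """
    if ismap is None:
        ismap = default_is_map()
    by_id = _check_meta(table, meta)
    entry = ismap.entry(PSY_CLASS)
    if psy_row not in table.areas.index:
        # fall back to any row whose class parses to PSY
        candidates = [
            r
            for r in table.analyte_rows
            if r.split(None, 1)[0] == PSY_CLASS
        ]
        if not candidates:
            raise MissingInternalStandardError("no psychosine row in the table")
        psy_row = candidates[0]
    if entry.species not in table.areas.index:
        raise MissingInternalStandardError(
            f"psychosine standard row {entry.species!r} missing"
        )
    is_area = table.areas.loc[entry.species]
    zero = is_area[is_area <= 0]
    if len(zero):
        raise ZeroInternalStandardAreaError(
            f"PSY standard zero in sample(s) {list(zero.index)}"
        )
    conc = table.areas.loc[psy_row] / is_area * ismap.spike(PSY_CLASS)
    out = pd.Series(
        {
            s: conc[s] * by_id[s].extract_volume / by_id[s].protein_amount
            for s in table.samples
        },
        name="PSY (ng/ug protein)",
    )
    return out


def handle_missing(
    matrix: ConcentrationMatrix,
    strategy: str = "none",
    presence_threshold: float = 0.5,
) -> ConcentrationMatrix:
    """Deterministic treatment of zero/missing cells.

    strategies
      ``none``
          pass-through (default; matching an analysis that reports raw
          semi-quantified values).
      ``half-min``
          zeros and NaNs replaced by half the smallest positive value of
          that species; species with no positive value raise
          :class:`AllMissingSpeciesError`.
      ``presence-filter``
          drop species detected (value > 0) in fewer than
          ``presence_threshold`` of samples.
    """
    values = matrix.values.copy()
    if strategy == "none":
        return matrix
    if strategy == "half-min":
        arr = values.to_numpy(dtype=float)
        imputed = 0
        for i in range(arr.shape[0]):
            row = arr[i]
            mask = ~(row > 0) | np.isnan(row)
            if mask.all():
                raise AllMissingSpeciesError(
                    f"species {values.index[i]!r} has no positive measurement"
                )
            if mask.any():
                row[mask] = row[~mask].min() / 2.0
                imputed += int(mask.sum())
        if imputed:
            logger.info("half-min imputation filled %d cells", imputed)
        out = pd.DataFrame(arr, index=values.index, columns=values.columns)
        return ConcentrationMatrix(out, matrix.meta, matrix.units, matrix.provenance)
    if strategy == "presence-filter":
        present = (values > 0).sum(axis=1) / values.shape[1]
        keep = present >= presence_threshold
        dropped = values.index[~keep].tolist()
        if dropped:
            logger.info("presence filter dropped %d species", len(dropped))
        return ConcentrationMatrix(
            values.loc[keep], matrix.meta, matrix.units, matrix.provenance
        )
    raise ValueError(f"unknown missing-value strategy {strategy!r}")
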