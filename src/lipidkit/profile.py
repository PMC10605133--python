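"""Class-level aggregation and two-group / multi-group comparison.

Species concentrations are grouped by lipid class and summed per sample;
classes are then compared between the case (HOM) and control (WT) groups
with a two-sided t-test (Welch by default).  Significance stars follow the
conventional bands: * p < 0.05, ** p < 0.01, *** p < 0.001.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, TooFewSamplesError
from .nomenclature import LipidClassInfo, default_registry, parse_lipid_name
from .quantify import ConcentrationMatrix, SampleMeta

__all__ = [
    "ClassTotals",
    "class_totals",
    "stars_for_p",
    "compare_groups",
    "anova_groups",
    "profile_table",
]

GRAND_TOTAL = "Total"


@dataclass
class ClassTotals:
    """Per-class summed concentrations (class x samples) plus the per-sample
    grand total."""

    values: pd.DataFrame
    grand_total: pd.Series

    def with_total_row(self) -> pd.DataFrame:
        out = self.values.copy()
        out.loc[GRAND_TOTAL] = self.grand_total
        return out


def species_classes(
    names: Sequence[str], registry: Mapping[str, LipidClassInfo] | None = None
) -> pd.Series:
    if registry is None:
        registry = default_registry()
    return pd.Series(
        {n: parse_lipid_name(n, registry).class_code for n in names}, name="class"
    )


def class_totals(
    matrix: ConcentrationMatrix | pd.DataFrame,
    registry: Mapping[str, LipidClassInfo] | None = None,
) -> ClassTotals:
    """Sum species concentrations within each lipid class, per sample."""
    values = matrix.values if isinstance(matrix, ConcentrationMatrix) else matrix
    classes = species_classes(list(values.index), registry)
    totals = values.groupby(classes).sum()
    totals = totals.sort_index()
    grand = totals.sum(axis=0)
    grand.name = GRAND_TOTAL
    return ClassTotals(values=totals, grand_total=grand)


def stars_for_p(p: float) -> str:
    """Significance stars; pure and monotone in p."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _group_columns(
    meta: Sequence[SampleMeta], case: str, control: str
) -> tuple[list[str], list[str]]:
    case_ids = [m.sample_id for m in meta if m.group == case]
    control_ids = [m.sample_id for m in meta if m.group == control]
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise TooFewSamplesError(
            f"need n >= 2 per group, got {control}:{len(control_ids)} "
            f"{case}:{len(case_ids)}"
        )
    return case_ids, control_ids


def compare_groups(
    data: pd.DataFrame | ClassTotals,
    meta: Sequence[SampleMeta],
    test: str = "welch",
    transform: str = "none",
    case: str = "HOM",
    control: str = "WT",
) -> pd.DataFrame:
    """Two-sided two-sample comparison of every row between groups.

    Returns a frame indexed like ``data`` with columns ``mean_<control>``,
    ``mean_<case>``, ``sd_*``, ``sem_*``, ``log2_fc``, ``p``, ``stars`` and
    per-group percent composition.  Items with zero variance in both groups
    get ``p = NaN`` (degenerate; reported, not raised, so one flat species
    does not abort a table-wide scan) — unless the two group means also
    differ, which is a genuine degenerate-variance error.
    """
    if isinstance(data, ClassTotals):
        data = data.values
    if test not in ("welch", "student"):
        raise ValueError(f"unknown test {test!r}")
    if transform not in ("none", "log"):
        raise ValueError(f"unknown transform {transform!r}")
    case_ids, control_ids = _group_columns(meta, case, control)

    raw_case = data[case_ids].to_numpy(dtype=float)
    raw_ctrl = data[control_ids].to_numpy(dtype=float)
    if transform == "log":
        with np.errstate(divide="ignore"):
            x_case, x_ctrl = np.log(raw_case), np.log(raw_ctrl)
    else:
        x_case, x_ctrl = raw_case, raw_ctrl

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(
            x_case, x_ctrl, axis=1, equal_var=(test == "student")
        )

    mean_ctrl = raw_ctrl.mean(axis=1)
    mean_case = raw_case.mean(axis=1)
    sd_ctrl = raw_ctrl.std(axis=1, ddof=1)
    sd_case = raw_case.std(axis=1, ddof=1)
    degenerate = (sd_ctrl == 0) & (sd_case == 0)
    if np.any(degenerate & (mean_case != mean_ctrl)):
        bad = data.index[degenerate & (mean_case != mean_ctrl)].tolist()
        raise DegenerateVarianceError(
            f"zero variance in both groups with unequal means for {bad}"
        )
    p = np.where(degenerate, np.nan, p)
    t = np.where(degenerate, np.nan, t)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.log2(mean_case / mean_ctrl)
    pct_ctrl = 100.0 * mean_ctrl / mean_ctrl.sum() if mean_ctrl.sum() > 0 else mean_ctrl
    pct_case = 100.0 * mean_case / mean_case.sum() if mean_case.sum() > 0 else mean_case

    return pd.DataFrame(
        {
            f"mean_{control}": mean_ctrl,
            f"mean_{case}": mean_case,
            f"sd_{control}": sd_ctrl,
            f"sd_{case}": sd_case,
            f"sem_{control}": sd_ctrl / np.sqrt(len(control_ids)),
            f"sem_{case}": sd_case / np.sqrt(len(case_ids)),
            f"pct_{control}": pct_ctrl,
            f"pct_{case}": pct_case,
            "log2_fc": log2_fc,
            "t": t,
            "p": p,
            "stars": [stars_for_p(v) for v in p],
        },
        index=data.index,
    )


def anova_groups(
    data: pd.DataFrame | ClassTotals,
    meta: Sequence[SampleMeta],
    transform: str = "none",
) -> pd.DataFrame:
    """One-way ANOVA across all group labels present in ``meta``."""
    if isinstance(data, ClassTotals):
        data = data.values
    groups: dict[str, list[str]] = {}
    for m in meta:
        groups.setdefault(m.group, []).append(m.sample_id)
    if len(groups) < 2:
        raise TooFewSamplesError("ANOVA needs at least two groups")
    for g, ids in groups.items():
        if len(ids) < 2:
            raise TooFewSamplesError(f"group {g!r} has n < 2")
    arrays = []
    for ids in groups.values():
        arr = data[ids].to_numpy(dtype=float)
        if transform == "log":
            with np.errstate(divide="ignore"):
                arr = np.log(arr)
        arrays.append(arr)
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*arrays, axis=1)
    return pd.DataFrame(
        {"F": f, "p": p, "stars": [stars_for_p(v) for v in p]}, index=data.index
    )


def profile_table(
    matrix: ConcentrationMatrix,
    test: str = "welch",
    transform: str = "none",
    case: str = "HOM",
    control: str = "WT",
    registry: Mapping[str, LipidClassInfo] | None = None,
) -> pd.DataFrame:
    """Class-level summary table: per-class group means, dispersion, p,
    stars and percent composition, plus a grand-total row.

    The grand-total p is a t-test on the per-sample total lipid
    concentration.
    """
    totals = class_totals(matrix, registry)
    table = compare_groups(totals.values, matrix.meta, test, transform, case, control)
    total_row = compare_groups(
        totals.grand_total.to_frame().T, matrix.meta, test, transform, case, control
    )
    total_row.index = [GRAND_TOTAL]
    # percent composition of the total row is 100 by construction; blank it
    total_row[f"pct_{control}"] = np.nan
    total_row[f"pct_{case}"] = np.nan
    return pd.concat([table, total_row])
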