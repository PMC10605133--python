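"""Correlation of psychosine with lipid-class totals across samples.

Psychosine, the cytotoxic lysosphingolipid that accumulates when GALC
activity is lost, is correlated against each class total over the pooled
cohort (both groups), and each class receives a signed association label.
Pearson on log-transformed concentrations is the default; Spearman is
available when monotone-but-nonlinear association is expected.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantVectorError, TooFewSamplesError
from .profile import ClassTotals

__all__ = ["psy_class_correlation"]


def psy_class_correlation(
    psy: pd.Series,
    totals: ClassTotals | pd.DataFrame,
    method: str = "pearson",
    log_transform: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate per-sample psychosine with every class total.

    Returns a frame indexed by class with ``coefficient``, ``p`` and a
    ``sign`` label (``positive`` / ``negative`` at significance ``alpha``,
    else ``none``).  Classes or PSY vectors with zero variance raise
    :class:`ConstantVectorError`.
    """
    values = totals.values if isinstance(totals, ClassTotals) else totals
    common = [s for s in values.columns if s in psy.index]
    if len(common) < 3:
        raise TooFewSamplesError("correlation needs >= 3 paired samples")
    x = psy.loc[common].to_numpy(dtype=float)
    if log_transform and method == "pearson":
        if (x <= 0).any():
            raise ValueError("log transform requires positive psychosine values")
        x = np.log(x)
    if np.std(x) == 0:
        raise ConstantVectorError("psychosine vector is constant")

    records = []
    for cls in values.index:
        y = values.loc[cls, common].to_numpy(dtype=float)
        if np.std(y) == 0:
            raise ConstantVectorError(f"class {cls!r} total is constant")
        if log_transform and method == "pearson":
            if (y <= 0).any():
                raise ValueError(f"log transform requires positive totals ({cls})")
            y_t = np.log(y)
        else:
            y_t = y
        if method == "pearson":
            r, p = stats.pearsonr(x, y_t)
        elif method == "spearman":
            r, p = stats.spearmanr(x, y_t)
        else:
            raise ValueError(f"unknown method {method!r}")
        if p < alpha:
            sign = "positive" if r > 0 else "negative"
        else:
            sign = "none"
        records.append({"class": cls, "method": method, "coefficient": r, "p": p, "sign": sign})
    return pd.DataFrame.from_records(records).set_index("class")
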