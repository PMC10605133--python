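"""Multivariate profiling: normalisation, scaling, PCA and heatmap clustering.

Conventions follow standard metabolomics practice: samples are observations,
lipid species are variables.  The default pre-processing chain is median
normalisation of sample columns, then Pareto scaling of species rows
(centre, divide by sqrt of the standard deviation), then PCA.  Pareto
scaling damps the dominance of high-abundance lipids without flattening
the variance structure the way autoscaling does.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .errors import TooFewSamplesError, ZeroMedianError
from .quantify import SampleMeta

__all__ = [
    "ScaledMatrix",
    "PCAResult",
    "Ellipse",
    "HeatmapSpec",
    "normalize_median",
    "scale",
    "pca",
    "confidence_ellipse",
    "heatmap_select_cluster",
]


@dataclass
class ScaledMatrix:
    """Items x samples matrix with a record of the applied steps."""

    values: pd.DataFrame
    steps: tuple[str, ...] = ()


@dataclass
class PCAResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # items x components
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class Ellipse:
    """A 2-D confidence ellipse: centre, semi-axes and rotation (radians)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (n x 2) inside the ellipse."""
        pts = np.asarray(points, dtype=float) - np.asarray(self.center)
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, s], [-s, c]])
        local = pts @ rot.T
        a, b = self.semi_axes
        return (local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2 <= 1.0


@dataclass
class HeatmapSpec:
    """Top-k selection with standardized rows and dendrogram orders."""

    values: pd.DataFrame  # selected items x samples, row-standardized
    selected: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str] = field(default_factory=list)
    col_order: list[str] = field(default_factory=list)


def normalize_median(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by its median and restore the overall scale
    by the median of the sample medians.

    Removes per-sample global intensity factors; after the step every column
    has the same median.
    """
    medians = matrix.median(axis=0)
    if (medians <= 0).any():
        bad = medians.index[medians <= 0].tolist()
        raise ZeroMedianError(f"non-positive sample median(s): {bad}")
    target = float(np.median(medians.to_numpy()))
    return matrix.div(medians, axis=1) * target


def scale(matrix: pd.DataFrame, method: str = "pareto") -> ScaledMatrix:
    """Centre each item (row) and divide by sd (``autoscale``) or sqrt(sd)
    (``pareto``); ``none`` centres only.  Constant rows map to zeros.
    """
    if matrix.shape[1] < 2:
        raise TooFewSamplesError("scaling needs >= 2 samples")
    centred = matrix.sub(matrix.mean(axis=1), axis=0)
    sd = matrix.std(axis=1, ddof=1)
    if method == "none":
        return ScaledMatrix(centred, ("center",))
    if method == "autoscale":
        divisor = sd.copy()
    elif method == "pareto":
        divisor = np.sqrt(sd)
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    divisor[divisor == 0] = 1.0  # constant rows stay zero after centring
    return ScaledMatrix(centred.div(divisor, axis=0), ("center", method))


def pca(scaled: ScaledMatrix | pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA with samples as observations and a deterministic sign convention
    (the largest-magnitude loading of each component is positive)."""
    values = scaled.values if isinstance(scaled, ScaledMatrix) else scaled
    X = values.to_numpy(dtype=float).T  # samples x items
    n_samples, n_items = X.shape
    if n_samples < 3:
        raise TooFewSamplesError("PCA needs >= 3 samples")
    max_rank = min(n_samples - 1, n_items)
    if n_components is None:
        n_components = max_rank
    n_components = min(n_components, max_rank)

    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # items x components

    # sign convention: flip so the largest-|loading| entry is positive
    for j in range(n_components):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]

    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=values.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=values.index, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
        explained_variance=model.explained_variance_,
    )


def confidence_ellipse(
    scores: pd.DataFrame | np.ndarray,
    level: float = 0.95,
    components: tuple[int, int] = (0, 1),
) -> Ellipse:
    """Confidence ellipse of a group's 2-D scores from the sample covariance
    and the chi-square(2) quantile at ``level``."""
    arr = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, dtype=float)
    pts = arr[:, list(components)]
    if pts.shape[0] < 3:
        raise TooFewSamplesError("confidence ellipse needs >= 3 samples")
    centre = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    semi = np.sqrt(np.maximum(evals, 0.0) * q)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(
        center=(float(centre[0]), float(centre[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        angle=angle,
        level=level,
    )


def group_ellipses(
    result: PCAResult, meta: Sequence[SampleMeta], level: float = 0.95
) -> dict[str, Ellipse]:
    groups: dict[str, list[str]] = {}
    for m in meta:
        groups.setdefault(m.group, []).append(m.sample_id)
    return {
        g: confidence_ellipse(result.scores.loc[ids], level=level)
        for g, ids in groups.items()
        if len(ids) >= 3
    }


def heatmap_select_cluster(
    matrix: pd.DataFrame,
    comparison: pd.DataFrame,
    k: int = 50,
    metric: str = "euclidean",
    method: str = "complete",
) -> HeatmapSpec:
    """Select the top-``k`` most significant items and cluster them.

    Items are ranked by ascending p-value from ``comparison`` (a
    :func:`lipidkit.profile.compare_groups` frame); ties break by descending
    |log2 fold change| then by name, so selection is deterministic.  Selected
    rows are autoscaled for display and both axes are clustered with the
    given metric and linkage (Euclidean / complete by default).
    """
    ranking = (
        comparison.assign(_absfc=comparison["log2_fc"].abs())
        .reset_index(names="_name")
        .sort_values(
            by=["p", "_absfc", "_name"],
            ascending=[True, False, True],
            na_position="last",
        )
    )
    k_eff = min(k, len(ranking))
    selected = list(ranking["_name"].head(k_eff))

    sub = matrix.loc[selected]
    disp = scale(sub, "autoscale").values

    row_link = linkage(pdist(disp.to_numpy(), metric=metric), method=method)
    col_link = linkage(pdist(disp.to_numpy().T, metric=metric), method=method)
    row_order = [disp.index[i] for i in leaves_list(row_link)]
    col_order = [disp.columns[i] for i in leaves_list(col_link)]
    return HeatmapSpec(
        values=disp,
        selected=selected,
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=row_order,
        col_order=col_order,
    )
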