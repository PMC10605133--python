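"""Reaction-activation scoring over catalogued lipid transformations.

For a catalogued transformation reactant -> product, the per-sample *weight*
is the ratio of the product pool's abundance to the reactant pool's
abundance.  A shift of the weight distribution between case and control
groups is evidence that the transformation is more (activated) or less
(suppressed) active in the case group.  Weights are ratios, so they are
invariant to per-sample global scaling of the underlying concentrations.

Statistics are computed on log2 weights by default, which makes activation
and suppression exactly symmetric; each scored edge reports the two-sided
t-test p-value, the t statistic, and a Z-score defined as the signed probit
of the two-sided p (positive when the case-group mean weight is higher).
The Z definition is a deterministic, monotone-in-p summary chosen so edges
can be ranked on a common normal scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, EdgeClassAbsentError, TooFewSamplesError
from .profile import ClassTotals
from .quantify import SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionEdge",
    "ReactionCatalog",
    "default_class_catalog",
    "compute_weights",
    "score_reactions",
    "annotate_and_export",
]

CALL_ACTIVATED = "activated"
CALL_SUPPRESSED = "suppressed"
CALL_UNCHANGED = "unchanged"


@dataclass(frozen=True)
class ReactionEdge:
    """A directed reactant -> product transformation with its annotation."""

    reactant: str
    product: str
    enzyme: str = ""
    genes: str = ""

    def __post_init__(self) -> None:
        if self.reactant == self.product:
            raise ValueError(f"self-loop edge {self.reactant!r}")

    @property
    def label(self) -> str:
        return f"{self.reactant}->{self.product}"


@dataclass
class ReactionCatalog:
    edges: list[ReactionEdge]
    scope: str = "class"

    def __iter__(self):
        return iter(self.edges)

    def __len__(self) -> int:
        return len(self.edges)


def load_class_catalog(source) -> ReactionCatalog:
    df = pd.read_csv(source)
    edges = [
        ReactionEdge(
            reactant=str(r.reactant),
            product=str(r.product),
            enzyme=str(r.enzyme),
            genes=str(r.genes),
        )
        for r in df.itertuples()
    ]
    return ReactionCatalog(edges=edges, scope="class")


def default_class_catalog() -> ReactionCatalog:
    """The built-in class-level catalog of well-established phospholipid
    transformations (CDS, PLD, PSS, PLA and mitochondrial PG/CL routes)."""
    ref = resources.files("lipidkit.data").joinpath("class_reactions.csv")
    with ref.open() as fh:
        return load_class_catalog(fh)


def compute_weights(
    totals: ClassTotals | pd.DataFrame,
    catalog: ReactionCatalog,
    strict: bool = False,
) -> pd.DataFrame:
    """Per-edge, per-sample product/reactant weight matrix.

    Edges whose reactant or product class is absent from the totals are
    skipped with a warning (or raise when ``strict``).  Samples where either
    pool is non-positive get NaN for that edge.
    """
    values = totals.values if isinstance(totals, ClassTotals) else totals
    rows = {}
    for edge in catalog:
        if edge.reactant not in values.index or edge.product not in values.index:
            msg = f"edge {edge.label}: class absent from totals; skipped"
            if strict:
                raise EdgeClassAbsentError(msg)
            logger.warning(msg)
            continue
        num = values.loc[edge.product].to_numpy(dtype=float)
        den = values.loc[edge.reactant].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where((num > 0) & (den > 0), num / den, np.nan)
        rows[edge.label] = w
    return pd.DataFrame(rows, index=values.columns).T


def z_from_p(p: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Signed probit of the two-sided p-value: |Z| = Phi^-1(1 - p/2), with
    the sign of the case-minus-control mean difference."""
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(np.asarray(p, dtype=float) / 2.0)
    return np.sign(direction) * z


def score_reactions(
    weights: pd.DataFrame,
    meta: Sequence[SampleMeta],
    threshold: float = 0.05,
    case: str = "HOM",
    control: str = "WT",
    log_scale: bool = True,
    test: str = "student",
    catalog: ReactionCatalog | None = None,
) -> pd.DataFrame:
    """Score each edge's weights between groups and call the direction.

    Returns a frame indexed by edge label with group mean log2 weights, t,
    p, Z and the call (activated / suppressed / unchanged at ``threshold``).

    The default test is Student's pooled t: log weights of the two groups
    share a noise model, and at the small group sizes typical of these
    cohorts (4-6 per group) the pooled test holds the nominal type-I rate
    while Welch's runs conservative.  Pass ``test="welch"`` to drop the
    equal-variance assumption.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    case_ids = [m.sample_id for m in meta if m.group == case]
    ctrl_ids = [m.sample_id for m in meta if m.group == control]

    annot = {}
    if catalog is not None:
        annot = {e.label: e for e in catalog}

    records = []
    for label, row in weights.iterrows():
        wc = row[case_ids].to_numpy(dtype=float)
        ww = row[ctrl_ids].to_numpy(dtype=float)
        wc, ww = wc[~np.isnan(wc)], ww[~np.isnan(ww)]
        if len(wc) < 2 or len(ww) < 2:
            raise TooFewSamplesError(
                f"edge {label}: fewer than 2 defined weights in a group"
            )
        xc = np.log2(wc) if log_scale else wc
        xw = np.log2(ww) if log_scale else ww
        if xc.std(ddof=1) == 0 and xw.std(ddof=1) == 0:
            if xc.mean() == xw.mean():
                t, p = np.nan, np.nan
            else:
                raise DegenerateVarianceError(
                    f"edge {label}: zero variance in both groups, unequal means"
                )
        else:
            t, p = stats.ttest_ind(xc, xw, equal_var=(test == "student"))
        diff = xc.mean() - xw.mean()
        z = float(z_from_p(np.array([p]), np.array([diff]))[0]) if np.isfinite(p) else np.nan
        if np.isfinite(p) and p < threshold:
            call = CALL_ACTIVATED if diff > 0 else CALL_SUPPRESSED
        else:
            call = CALL_UNCHANGED
        edge = annot.get(label)
        records.append(
            {
                "edge": label,
                "reactant": edge.reactant if edge else label.split("->")[0],
                "product": edge.product if edge else label.split("->")[-1],
                "enzyme": edge.enzyme if edge else "",
                "genes": edge.genes if edge else "",
                f"mean_log2_weight_{control}": xw.mean() if log_scale else np.log2(ww).mean(),
                f"mean_log2_weight_{case}": xc.mean() if log_scale else np.log2(wc).mean(),
                "t": t,
                "p": p,
                "z": z,
                "call": call,
            }
        )
    out = pd.DataFrame.from_records(records)
    if len(out):
        out = out.set_index("edge")
    return out


def annotate_and_export(
    scores: pd.DataFrame,
    csv_path=None,
    graphml_path=None,
) -> nx.DiGraph:
    """Build the annotated directed reaction graph and optionally write the
    score table (CSV) and graph (GraphML).  Valid empty outputs are produced
    for an empty score table."""
    graph = nx.DiGraph()
    for label, row in scores.iterrows():
        graph.add_edge(
            row["reactant"],
            row["product"],
            enzyme=row.get("enzyme", ""),
            genes=row.get("genes", ""),
            p=float(row["p"]) if np.isfinite(row["p"]) else float("nan"),
            z=float(row["z"]) if np.isfinite(row["z"]) else float("nan"),
            t=float(row["t"]) if np.isfinite(row["t"]) else float("nan"),
            call=row["call"],
        )
    if csv_path is not None:
        scores.to_csv(csv_path)
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
    return graph
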