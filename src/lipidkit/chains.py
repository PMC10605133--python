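"""Fatty-acyl building-block analysis: chain abundances, length/unsaturation
profiles, and elongation / desaturation / beta-oxidation network scoring.

Every molecular species is decomposed into its chains; a chain's abundance
in a sample is the multiplicity-weighted sum of the concentrations of the
species that carry it.  Chain-level transformations are then scored with the
same product/reactant weight machinery as the class-level network:

* elongation      (c, d) -> (c+2, d)   ELOVL elongases
* desaturation    (c, d) -> (c, d+1)   SCD1 / FADS1 (D5D) / FADS2 (D6D)
* beta-oxidation  (c, d) -> (c-2, d)   generated for long substrates only

Edges are generated only between chains actually observed in the data.
Sphingoid long-chain bases (hydroxylated chains of sphingolipids) are
excluded by default so the analysis reflects fatty-acyl chains.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import ClassAbsentError
from .nomenclature import (
    LipidClassInfo,
    default_registry,
    parse_lipid_name,
)
from .profile import compare_groups
from .quantify import ConcentrationMatrix, SampleMeta
from .reactions import ReactionCatalog, ReactionEdge, compute_weights, score_reactions

__all__ = [
    "chain_label",
    "chain_abundance",
    "chain_profiles",
    "build_chain_catalog",
    "chain_network",
    "chain_network_within_class",
    "default_enzyme_lookup",
]


def chain_label(carbons: int, double_bonds: int) -> str:
    return f"{carbons}:{double_bonds}"


def _parse_label(label: str) -> tuple[int, int]:
    c, d = label.split(":")
    return int(c), int(d)


@dataclass
class EnzymeLookup:
    """(edge type, substrate chain) -> enzyme/gene annotation."""

    by_substrate: dict[tuple[str, str], tuple[str, str]]
    defaults: dict[str, tuple[str, str]]

    def annotate(self, kind: str, substrate: str) -> tuple[str, str]:
        if (kind, substrate) in self.by_substrate:
            return self.by_substrate[(kind, substrate)]
        return self.defaults.get(kind, ("", ""))


def load_enzyme_lookup(source) -> EnzymeLookup:
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    by_substrate = {}
    for kind in ("elongation", "desaturation", "beta_oxidation"):
        for substrate, entry in (doc.get(kind) or {}).items():
            by_substrate[(kind, str(substrate))] = (
                str(entry["enzyme"]),
                str(entry["genes"]),
            )
    defaults = {
        kind: (str(e["enzyme"]), str(e["genes"]))
        for kind, e in (doc.get("defaults") or {}).items()
    }
    return EnzymeLookup(by_substrate=by_substrate, defaults=defaults)


_DEFAULT_LOOKUP: EnzymeLookup | None = None


def default_enzyme_lookup() -> EnzymeLookup:
    global _DEFAULT_LOOKUP
    if _DEFAULT_LOOKUP is None:
        ref = resources.files("lipidkit.data").joinpath("chain_enzymes.yaml")
        with ref.open() as fh:
            _DEFAULT_LOOKUP = load_enzyme_lookup(fh)
    return _DEFAULT_LOOKUP


def chain_abundance(
    matrix: ConcentrationMatrix | pd.DataFrame,
    class_code: str | None = None,
    multiplicity: bool = True,
    include_sphingoid_bases: bool = False,
    registry: Mapping[str, LipidClassInfo] | None = None,
) -> pd.DataFrame:
    """Chain ("C:D") x samples abundance matrix.

    Sum-composition species cannot be decomposed and are skipped.  With
    ``multiplicity`` (default) a species carrying the same chain twice
    contributes its concentration twice to that chain.  Hydroxylated chains
    (sphingoid bases, ";O" acyls) are excluded unless requested.
    """
    values = matrix.values if isinstance(matrix, ConcentrationMatrix) else matrix
    if registry is None:
        registry = default_registry()

    acc: dict[str, pd.Series] = {}
    class_seen = False
    for raw in values.index:
        species = parse_lipid_name(raw, registry)
        if class_code is not None:
            if species.class_code != class_code:
                continue
            class_seen = True
        if species.annotation_level != "molecular-species":
            continue
        chains = species.chains if multiplicity else tuple(set(species.chains))
        for chain in chains:
            if chain.oxidation > 0 and not include_sphingoid_bases:
                continue
            label = chain_label(*chain.key)
            if label in acc:
                acc[label] = acc[label] + values.loc[raw]
            else:
                acc[label] = values.loc[raw].copy()
    if class_code is not None and not class_seen:
        raise ClassAbsentError(f"no species of class {class_code!r} in the matrix")
    out = pd.DataFrame(acc).T
    if len(out):
        out = out.loc[sorted(out.index, key=_parse_label)]
        out = out.reindex(columns=values.columns)
    return out


def chain_profiles(
    chain_ab: pd.DataFrame,
    meta: Sequence[SampleMeta],
    axis: str = "length",
    test: str = "welch",
    case: str = "HOM",
    control: str = "WT",
) -> pd.DataFrame:
    """Grouped histogram along chain length or unsaturation with per-bin
    group means, dispersion and t-test p-values.

    Bins aggregate over the other axis: the ``length`` profile sums all
    chains with a given carbon count regardless of saturation, and vice
    versa.
    """
    if axis not in ("length", "unsaturation"):
        raise ValueError(f"unknown axis {axis!r}")
    idx = 0 if axis == "length" else 1
    bins = pd.Series({label: _parse_label(label)[idx] for label in chain_ab.index})
    binned = chain_ab.groupby(bins).sum().sort_index()
    return compare_groups(binned, meta, test=test, case=case, control=control)


def build_chain_catalog(
    observed: Sequence[str],
    beta_oxidation: bool = True,
    beta_ox_min_carbons: int = 20,
    lookup: EnzymeLookup | None = None,
) -> ReactionCatalog:
    """Generate the chain transformation catalog restricted to observed
    chains.

    Beta-oxidation edges are limited to substrates with at least
    ``beta_ox_min_carbons`` carbons so that the ubiquitous C16/C18 pool does
    not saturate the network with shortening edges.
    """
    if lookup is None:
        lookup = default_enzyme_lookup()
    present = set(observed)
    edges = []

    def add(kind: str, sub: str, prod: str) -> None:
        enzyme, genes = lookup.annotate(kind, sub)
        edges.append(ReactionEdge(reactant=sub, product=prod, enzyme=enzyme, genes=genes))

    for label in sorted(present, key=_parse_label):
        c, d = _parse_label(label)
        elong = chain_label(c + 2, d)
        if elong in present:
            add("elongation", label, elong)
        desat = chain_label(c, d + 1)
        if desat in present:
            add("desaturation", label, desat)
        if beta_oxidation and c >= beta_ox_min_carbons:
            short = chain_label(c - 2, d)
            if short in present:
                add("beta_oxidation", label, short)
    return ReactionCatalog(edges=edges, scope="chain")


def chain_network(
    chain_ab: pd.DataFrame,
    meta: Sequence[SampleMeta],
    threshold: float = 0.05,
    case: str = "HOM",
    control: str = "WT",
    log_scale: bool = True,
    catalog: ReactionCatalog | None = None,
    **catalog_kwargs,
) -> pd.DataFrame:
    """Score elongation/desaturation/beta-oxidation edges over chain
    abundances; same weight/t/p/Z machinery as the class network."""
    if catalog is None:
        catalog = build_chain_catalog(list(chain_ab.index), **catalog_kwargs)
    weights = compute_weights(chain_ab, catalog)
    return score_reactions(
        weights,
        meta,
        threshold=threshold,
        case=case,
        control=control,
        log_scale=log_scale,
        catalog=catalog,
    )


def chain_network_within_class(
    matrix: ConcentrationMatrix,
    class_code: str,
    threshold: float = 0.05,
    case: str = "HOM",
    control: str = "WT",
    registry: Mapping[str, LipidClassInfo] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Chain network restricted to the species of a single lipid class
    (e.g. the PC-only or ether-PE-only remodelling network)."""
    chain_ab = chain_abundance(matrix, class_code=class_code, registry=registry)
    if chain_ab.empty or len(chain_ab.index) < 2:
        return pd.DataFrame(
            columns=[
                "reactant", "product", "enzyme", "genes",
                f"mean_log2_weight_{control}", f"mean_log2_weight_{case}",
                "t", "p", "z", "call",
            ]
        )
    return chain_network(
        chain_ab, matrix.meta, threshold=threshold, case=case, control=control, **kwargs
    )
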