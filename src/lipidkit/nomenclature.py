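"""Shorthand lipid nomenclature: parsing, formatting and acyl decomposition.

Lipid molecular species are written in the compact updated shorthand used by
modern annotation software, e.g. ``PC 16:0_18:1``, ``PE O-16:1_18:1``,
``SM 18:1;O2/16:0`` or ``CE 20:4``.  A name is a class token followed by one
chain token per sn-position (or per amide/base position for sphingolipids):

* ``C:D`` — a chain with ``C`` carbons and ``D`` double bonds;
* ``;O`` / ``;O2`` — hydroxylation count (sphingoid bases, hydroxy acyls);
* ``O-`` prefix — ether (alkyl) linkage; ``P-`` — plasmalogen (vinyl ether),
  stored as the equivalent ``O-`` chain with one extra double bond;
* ``_`` separates chains of unknown sn-position, ``/`` of known position;
* the legacy sphingolipid dialect ``d18:1`` / ``t18:1`` is accepted and
  normalised to ``18:1;O2`` / ``18:1;O3``.

A name carrying fewer chain tokens than the class requires is kept at
*sum-composition* level (e.g. ``SM 34:1``); such species participate in class
statistics but cannot be decomposed into building blocks.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import yaml

from .errors import (
    ChainCountMismatchError,
    MalformedChainError,
    SumCompositionError,
    UnknownClassError,
)

__all__ = [
    "Chain",
    "LipidClassInfo",
    "LipidSpecies",
    "load_registry",
    "default_registry",
    "parse_lipid_name",
    "format_lipid_name",
    "building_blocks",
]

# Classes whose plain code gains an "-O" suffix when the species is
# ether-linked (the ether subclasses are first-class registry entries).
_ETHER_VARIANTS = {"PC": "PC-O", "PE": "PE-O", "PI": "PI-O"}
_ETHER_BASES = {v: k for k, v in _ETHER_VARIANTS.items()}

_CHAIN_RE = re.compile(r"^(?P<lcb>[dt])?(?P<c>\d+):(?P<d>\d+)(?:;O(?P<ox>\d*))?$")


@dataclass(frozen=True)
class Chain:
    """A fatty-acyl or sphingoid chain: carbon count, double bonds,
    hydroxylation count and ether linkage."""

    carbons: int
    double_bonds: int
    oxidation: int = 0
    ether: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise MalformedChainError(f"chain needs >=1 carbon, got {self.carbons}")
        if self.double_bonds < 0 or self.double_bonds > self.carbons // 2:
            raise MalformedChainError(
                f"implausible double-bond count {self.double_bonds} for "
                f"{self.carbons} carbons"
            )
        if self.oxidation < 0:
            raise MalformedChainError("negative hydroxylation count")

    @property
    def key(self) -> tuple[int, int]:
        """(carbons, double_bonds) signature used for building-block work."""
        return (self.carbons, self.double_bonds)

    def __str__(self) -> str:
        s = f"{self.carbons}:{self.double_bonds}"
        if self.oxidation == 1:
            s += ";O"
        elif self.oxidation > 1:
            s += f";O{self.oxidation}"
        if self.ether:
            s = "O-" + s
        return s


@dataclass(frozen=True)
class LipidClassInfo:
    code: str
    full_name: str
    expected_chains: int
    category: str


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid molecular species (or sum composition)."""

    class_code: str
    chains: tuple[Chain, ...]
    sn_positions_known: bool = False
    annotation_level: str = "molecular-species"  # or "sum-composition"
    raw_name: str = field(default="", compare=False)

    @property
    def is_ether(self) -> bool:
        return any(c.ether for c in self.chains)


def load_registry(source) -> dict[str, LipidClassInfo]:
    """Load a class registry from a YAML mapping (path or file object)."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    registry: dict[str, LipidClassInfo] = {}
    for entry in doc["classes"]:
        info = LipidClassInfo(
            code=str(entry["code"]),
            full_name=str(entry["full_name"]),
            expected_chains=int(entry["chains"]),
            category=str(entry["category"]),
        )
        if info.code in registry:
            raise ValueError(f"duplicate class code {info.code!r}")
        registry[info.code] = info
    return registry


_DEFAULT_REGISTRY: dict[str, LipidClassInfo] | None = None


def default_registry() -> dict[str, LipidClassInfo]:
    """The built-in 20-class registry (19 profile classes + PSY)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        ref = resources.files("lipidkit.data").joinpath("class_registry.yaml")
        with ref.open() as fh:
            _DEFAULT_REGISTRY = load_registry(fh)
    return dict(_DEFAULT_REGISTRY)


def _parse_chain(token: str) -> Chain:
    ether = False
    extra_db = 0
    if token.startswith("O-"):
        ether = True
        token = token[2:]
    elif token.startswith("P-"):
        # plasmalogen == alkenyl ether: O- chain with one more double bond
        ether = True
        extra_db = 1
        token = token[2:]
    m = _CHAIN_RE.match(token)
    if m is None:
        raise MalformedChainError(f"bad chain token {token!r}")
    oxidation = 0
    if m.group("lcb"):
        oxidation = 2 if m.group("lcb") == "d" else 3
    if m.group("ox") is not None:
        oxidation = int(m.group("ox")) if m.group("ox") else 1
    return Chain(
        carbons=int(m.group("c")),
        double_bonds=int(m.group("d")) + extra_db,
        oxidation=oxidation,
        ether=ether,
    )


def parse_lipid_name(
    name: str, registry: Mapping[str, LipidClassInfo] | None = None
) -> LipidSpecies:
    """Parse a shorthand name into a :class:`LipidSpecies`.

    Raises :class:`UnknownClassError`, :class:`MalformedChainError` or
    :class:`ChainCountMismatchError` on invalid input.
    """
    if registry is None:
        registry = default_registry()
    name = name.strip()
    if not name:
        raise MalformedChainError("empty lipid name")
    parts = name.split(None, 1)
    class_token = parts[0]
    if class_token not in registry:
        raise UnknownClassError(f"unknown lipid class {class_token!r} in {name!r}")
    rest = parts[1] if len(parts) > 1 else ""
    if not rest:
        raise MalformedChainError(f"no chain information in {name!r}")

    sn_known = "/" in rest
    tokens = re.split(r"[/_]", rest)
    chains = tuple(_parse_chain(tok) for tok in tokens)

    class_code = class_token
    if chains and chains[0].ether and class_token in _ETHER_VARIANTS:
        class_code = _ETHER_VARIANTS[class_token]
    info = registry.get(class_code)
    if info is None:
        raise UnknownClassError(f"unknown lipid class {class_code!r} in {name!r}")

    if len(chains) == info.expected_chains:
        level = "molecular-species"
    elif len(chains) == 1 and info.expected_chains > 1:
        level = "sum-composition"
    else:
        raise ChainCountMismatchError(
            f"{name!r}: {len(chains)} chains given, {info.expected_chains} "
            f"expected for class {class_code}"
        )
    return LipidSpecies(
        class_code=class_code,
        chains=chains,
        sn_positions_known=sn_known,
        annotation_level=level,
        raw_name=name,
    )


def format_lipid_name(species: LipidSpecies) -> str:
    """Render a species back to canonical shorthand.

    Ether subclasses are written in the ``PE O-16:1_18:1`` dialect (plain
    class token, ``O-`` prefix on the ether chain); hydroxylations use the
    ``;O``/``;O2`` suffix.  ``parse_lipid_name(format_lipid_name(s)) == s``
    for every valid species.
    """
    base = _ETHER_BASES.get(species.class_code, species.class_code)
    sep = "/" if species.sn_positions_known else "_"
    return f"{base} {sep.join(str(c) for c in species.chains)}"


def building_blocks(species: LipidSpecies) -> list[tuple[int, int]]:
    """Decompose a molecular species into its (carbons, double_bonds) chain
    signatures, preserving multiplicity.

    Raises :class:`SumCompositionError` for sum-composition annotations,
    whose total C:D cannot be attributed to individual chains.
    """
    if species.annotation_level != "molecular-species":
        raise SumCompositionError(
            f"{species.raw_name or species.class_code}: sum-composition species "
            "cannot be decomposed into building blocks"
        )
    return [c.key for c in species.chains]


def parse_many(
    names: Iterable[str], registry: Mapping[str, LipidClassInfo] | None = None
) -> dict[str, LipidSpecies]:
    """Parse a list of names, returning a name -> species mapping."""
    if registry is None:
        registry = default_registry()
    return {n: parse_lipid_name(n, registry) for n in names}


def as_sum_composition(species: LipidSpecies) -> LipidSpecies:
    """Collapse a molecular species to its sum composition (total C:D)."""
    if species.annotation_level == "sum-composition":
        return species
    total = Chain(
        carbons=sum(c.carbons for c in species.chains),
        double_bonds=sum(c.double_bonds for c in species.chains),
        oxidation=sum(c.oxidation for c in species.chains),
        ether=species.is_ether,
    )
    return replace(
        species, chains=(total,), annotation_level="sum-composition", raw_name=""
    )
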