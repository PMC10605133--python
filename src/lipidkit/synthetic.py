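"""Synthetic lipidomics cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a two-group design (control WT vs case HOM) with small n per group;
* ~18-19 lipid classes whose control-group mean totals default to a bundled
  reference profile of mouse nervous-tissue class concentrations, and whose
  case/control effect ratios default to the matching reference ratios;
* species within a class share the class total through a fixed Dirichlet
  split, so class totals are controlled while species vary;
* multiplicative log-normal noise with a configurable coefficient of
  variation (mean-one multipliers, so expected totals hit the design
  targets exactly and the zero-CV limit is deterministic);
* fatty-acyl chains drawn from a pool concentrated on C16/C18 chains with
  zero or one double bond, matching what dominates nervous-tissue lipids;
* a psychosine level per sample with a tissue-specific case/control ratio.

Planted effects (a class-level product fold change, or a chain-level fold
change realised through homo-acyl species) are recorded in a
:class:`GroundTruth` object so downstream calls can be scored for recovery.

Feature tables are constructed by inverting the internal-standard
semi-quantification formula, so ``semiquantify`` recovers the underlying
concentration matrix to floating-point accuracy.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, UnknownEdgeError
from .nomenclature import (
    Chain,
    LipidClassInfo,
    LipidSpecies,
    default_registry,
    format_lipid_name,
    parse_lipid_name,
)
from .quantify import (
    ConcentrationMatrix,
    FeatureTable,
    ISMap,
    SampleMeta,
    default_is_map,
)

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "SyntheticDataset",
    "default_design",
    "null_design",
    "plant_reaction_effect",
    "generate_concentrations",
    "generate_feature_table",
    "reference_class_profiles",
]

# Chain pool: (carbons, double_bonds) -> sampling weight.  Concentrated on
# C16/C18 with 0-1 double bonds; the long tail covers the PUFA and very-long
# saturated chains seen in nervous tissue.
DEFAULT_CHAIN_POOL: tuple[tuple[tuple[int, int], float], ...] = (
    ((16, 0), 0.18),
    ((16, 1), 0.08),
    ((18, 0), 0.16),
    ((18, 1), 0.22),
    ((18, 2), 0.10),
    ((20, 1), 0.04),
    ((20, 4), 0.07),
    ((22, 0), 0.04),
    ((22, 6), 0.05),
    ((24, 0), 0.03),
    ((24, 1), 0.03),
)

SPHINGOID_BASE = Chain(carbons=18, double_bonds=1, oxidation=2)
SPHINGOLIPID_CLASSES = {"Cer", "SM", "HexCer", "SHexCer"}
ETHER_CLASSES = {"PC-O", "PE-O", "PI-O"}

# Psychosine design per tissue: control-group level (ng/ug protein) and
# case/control ratio.  The SC/SN ratios mirror the published ~22x/~27x
# accumulation; CNS tissues accumulate less.
PSY_DEFAULTS: dict[str, tuple[float, float]] = {
    "B": (0.08, 5.0),
    "C": (0.10, 8.0),
    "SC": (0.15, 22.0),
    "SN": (0.20, 27.0),
}

PSY_SPECIES_NAME = "PSY 18:1;O2"


def reference_class_profiles() -> pd.DataFrame:
    """The bundled per-tissue reference of class mean concentrations
    (ug/ug protein) for control and case groups with significance stars."""
    ref = resources.files("lipidkit.data").joinpath("reference_class_profiles.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    df["stars"] = df["stars"].astype(str)
    return df


# One canonical molecular species per class, used to feed class-mean tables
# through the species-level machinery (each class is represented by a single
# carrier species holding the class mean).
REPRESENTATIVE_SPECIES: dict[str, str] = {
    "CE": "CE 18:1",
    "Cer": "Cer 18:1;O2/16:0",
    "CL": "CL 18:1_18:1_18:1_18:1",
    "DG": "DG 16:0_18:1",
    "PC-O": "PC O-16:0_18:1",
    "PE-O": "PE O-16:1_18:1",
    "PI-O": "PI O-16:0_18:1",
    "HexCer": "HexCer 18:1;O2/24:0",
    "LPC": "LPC 18:1",
    "LPE": "LPE 18:0",
    "LPI": "LPI 20:4",
    "PA": "PA 18:0_18:1",
    "PC": "PC 16:0_18:1",
    "PE": "PE 18:0_20:4",
    "PG": "PG 16:0_18:1",
    "PI": "PI 18:0_20:4",
    "PS": "PS 18:0_18:1",
    "SHexCer": "SHexCer 18:1;O2/24:1",
    "SM": "SM 18:1;O2/16:0",
}


def reference_species_matrix(tissue: str) -> pd.DataFrame:
    """The bundled reference class means as a species-keyed matrix.

    Each class's mean concentration is assigned to one representative
    molecular species, giving a matrix (species x {WT_mean, HOM_mean}) that
    the class-aggregation machinery can consume directly; its grand totals
    are then the reference profile's printed totals.
    """
    ref = reference_class_profiles()
    sub = ref[ref["tissue"] == tissue]
    if sub.empty:
        raise InvalidDesignError(f"unknown tissue {tissue!r}")
    rows = {
        REPRESENTATIVE_SPECIES[row.class_code]: {
            "WT_mean": row.wt_mean,
            "HOM_mean": row.hom_mean,
        }
        for row in sub.itertuples()
    }
    return pd.DataFrame(rows).T


@dataclass(frozen=True)
class SyntheticDesign:
    """Everything needed to generate a reproducible synthetic cohort."""

    tissue: str
    class_baselines: Mapping[str, float]
    class_effect_ratios: Mapping[str, float]
    species_per_class: int = 13
    chain_pool: tuple[tuple[tuple[int, int], float], ...] = DEFAULT_CHAIN_POOL
    cv: float = 0.20
    n_control: int = 5
    n_case: int = 4
    control_label: str = "WT"
    case_label: str = "HOM"
    psy_control: float = 0.20
    psy_ratio: float = 27.0
    seed: int = 0
    planted_class_effects: tuple[tuple[str, str, float], ...] = ()  # (reactant, product, fold)
    planted_chain_effects: tuple[tuple[str, str, float], ...] = ()  # (sub "C:D", prod "C:D", fold)

    def __post_init__(self) -> None:
        if not self.class_baselines:
            raise InvalidDesignError("no class baselines")
        for cls, v in self.class_baselines.items():
            if v <= 0:
                raise InvalidDesignError(f"baseline for {cls} must be > 0")
        for cls, r in self.class_effect_ratios.items():
            if r <= 0:
                raise InvalidDesignError(f"effect ratio for {cls} must be > 0")
        if self.cv < 0:
            raise InvalidDesignError("cv must be >= 0")
        if self.n_control < 2 or self.n_case < 2:
            raise InvalidDesignError("need n >= 2 per group")
        if self.psy_control <= 0 or self.psy_ratio <= 0:
            raise InvalidDesignError("psychosine design must be positive")


@dataclass
class GroundTruth:
    """Planted structure sufficient to score every downstream call."""

    class_effect_ratios: dict[str, float]
    planted_class_edges: list[dict]
    planted_chain_edges: list[dict]
    psy_ratio: float
    psy: pd.Series
    species_means: pd.Series  # control-group expected species concentrations
    seed: int


@dataclass
class SyntheticDataset:
    """A generated cohort: feature table + the concentrations it encodes."""

    table: FeatureTable
    concentrations: ConcentrationMatrix
    psy: pd.Series
    ground_truth: GroundTruth

    @property
    def meta(self) -> list[SampleMeta]:
        return self.concentrations.meta


def default_design(tissue: str = "SN", seed: int = 0, **overrides) -> SyntheticDesign:
    """Design whose baselines and effect ratios follow the bundled reference
    profile for the given tissue (B, C, SC or SN)."""
    ref = reference_class_profiles()
    sub = ref[ref["tissue"] == tissue]
    if sub.empty:
        raise InvalidDesignError(f"unknown tissue {tissue!r}")
    baselines = dict(zip(sub["class_code"], sub["wt_mean"]))
    ratios = {
        row.class_code: row.hom_mean / row.wt_mean for row in sub.itertuples()
    }
    psy_control, psy_ratio = PSY_DEFAULTS[tissue]
    kwargs = dict(
        tissue=tissue,
        class_baselines=baselines,
        class_effect_ratios=ratios,
        psy_control=psy_control,
        psy_ratio=psy_ratio,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticDesign(**kwargs)


def null_design(tissue: str = "SN", seed: int = 0, **overrides) -> SyntheticDesign:
    """Same class baselines as :func:`default_design` but with every effect
    ratio (including psychosine) set to 1: no group difference at all."""
    design = default_design(tissue=tissue, seed=seed)
    kwargs = dict(
        tissue=tissue,
        class_baselines=design.class_baselines,
        class_effect_ratios={c: 1.0 for c in design.class_baselines},
        psy_control=design.psy_control,
        psy_ratio=1.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticDesign(**kwargs)


def plant_reaction_effect(
    design: SyntheticDesign, edge: tuple[str, str], fold_change: float
) -> SyntheticDesign:
    """Return a design with the product side of ``edge`` scaled by
    ``fold_change`` in the case group.

    ``edge`` is a (reactant, product) pair of class codes (e.g.
    ``("PA", "PG")``) or of chain labels (e.g. ``("18:1", "18:2")``).
    """
    if fold_change <= 0:
        raise InvalidDesignError("fold change must be > 0")
    reactant, product = edge
    if ":" in product:  # chain-level edge
        pool_labels = {f"{c}:{d}" for (c, d), _ in design.chain_pool}
        for label in (reactant, product):
            if label not in pool_labels:
                raise UnknownEdgeError(f"chain {label!r} not in the design pool")
        if fold_change == 1.0:
            return design  # a unit fold change is no effect at all
        return dataclasses.replace(
            design,
            planted_chain_effects=design.planted_chain_effects
            + ((reactant, product, float(fold_change)),),
        )
    for cls in (reactant, product):
        if cls not in design.class_baselines:
            raise UnknownEdgeError(f"class {cls!r} not in the design")
    if fold_change == 1.0:
        return design
    return dataclasses.replace(
        design,
        planted_class_effects=design.planted_class_effects
        + ((reactant, product, float(fold_change)),),
    )


def _sample_species_names(
    design: SyntheticDesign,
    registry: Mapping[str, LipidClassInfo],
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Draw unique, parseable species names per class from the chain pool."""
    keys = [k for k, _ in design.chain_pool]
    weights = np.array([w for _, w in design.chain_pool], dtype=float)
    weights = weights / weights.sum()
    chain_cache = {
        (i, ether): Chain(carbons=keys[i][0], double_bonds=keys[i][1], ether=ether)
        for i in range(len(keys))
        for ether in (False, True)
    }

    out: dict[str, list[str]] = {}
    for cls in design.class_baselines:
        info = registry.get(cls)
        if info is None:
            raise InvalidDesignError(f"class {cls!r} not in registry")
        # chains drawn per species: sphingolipids have a fixed base
        n_drawn = info.expected_chains - (1 if cls in SPHINGOLIPID_CLASSES else 0)
        # cap the target at the number of distinct names achievable
        if n_drawn == 1:
            target = min(design.species_per_class, len(keys))
        else:
            target = design.species_per_class
        names: list[str] = []
        seen: set[str] = set()
        for _round in range(8):
            if len(names) >= target:
                break
            draws = rng.choice(len(keys), size=(4 * target, n_drawn), p=weights)
            for row in draws:
                if len(names) >= target:
                    break
                if cls in SPHINGOLIPID_CLASSES:
                    chains = (SPHINGOID_BASE,) + tuple(
                        chain_cache[(i, False)] for i in row
                    )
                    sn_known = True
                elif cls in ETHER_CLASSES:
                    acyls = sorted(
                        (chain_cache[(i, False)] for i in row[1:]),
                        key=lambda ch: ch.key,
                    )
                    chains = (chain_cache[(row[0], True)], *acyls)
                    sn_known = False
                else:
                    chains = tuple(
                        sorted(
                            (chain_cache[(i, False)] for i in row),
                            key=lambda ch: ch.key,
                        )
                    )
                    sn_known = False
                species = LipidSpecies(
                    class_code=cls, chains=chains, sn_positions_known=sn_known
                )
                name = format_lipid_name(species)
                if name not in seen:
                    seen.add(name)
                    names.append(name)
        out[cls] = names
    return out


def _homo_acyl_name(cls: str, info: LipidClassInfo, label: str) -> str:
    c, d = label.split(":")
    chain = Chain(carbons=int(c), double_bonds=int(d))
    species = LipidSpecies(class_code=cls, chains=(chain,) * info.expected_chains)
    return format_lipid_name(species)


def _apply_chain_planting(
    species_by_class: dict[str, list[str]],
    design: SyntheticDesign,
    registry: Mapping[str, LipidClassInfo],
) -> dict[str, list[str]]:
    """Guarantee homo-acyl carriers for every planted chain.

    A species-level multiplier cannot move one chain's abundance without
    dragging its partner chains along, so chain effects are realised through
    species composed solely of the planted chain.  The first species of each
    two-chain glycerophospholipid/glycerolipid class is converted to the
    homo-acyl form of the planted product chain (deduplicated if already
    present).
    """
    planted = {prod for _, prod, _ in design.planted_chain_effects}
    if not planted:
        return species_by_class
    out = {cls: list(names) for cls, names in species_by_class.items()}
    for label in sorted(planted):
        for cls, names in out.items():
            info = registry[cls]
            if info.expected_chains != 2 or cls in SPHINGOLIPID_CLASSES or cls in ETHER_CLASSES:
                continue
            homo = _homo_acyl_name(cls, info, label)
            if homo not in names:
                names[0] = homo
    return out


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)
    return np.exp(rng.normal(loc=-sigma2 / 2.0, scale=sigma, size=size))


def _make_meta(design: SyntheticDesign) -> list[SampleMeta]:
    meta = [
        SampleMeta(
            sample_id=f"{design.control_label}{i + 1}",
            group=design.control_label,
            tissue=design.tissue,
        )
        for i in range(design.n_control)
    ]
    meta += [
        SampleMeta(
            sample_id=f"{design.case_label}{i + 1}",
            group=design.case_label,
            tissue=design.tissue,
        )
        for i in range(design.n_case)
    ]
    return meta


def generate_concentrations(
    design: SyntheticDesign,
    registry: Mapping[str, LipidClassInfo] | None = None,
) -> tuple[ConcentrationMatrix, GroundTruth]:
    """Generate a species x samples concentration matrix plus ground truth.

    Expected class totals equal the design baselines in the control group
    and baseline x effect ratio (x any planted fold) in the case group;
    the zero-CV limit realises those targets exactly.
    """
    if registry is None:
        registry = default_registry()
    rng_struct = np.random.default_rng([design.seed, 0])
    rng_noise = np.random.default_rng([design.seed, 1])
    rng_psy = np.random.default_rng([design.seed, 2])

    species_by_class = _sample_species_names(design, registry, rng_struct)
    species_by_class = _apply_chain_planting(species_by_class, design, registry)

    meta = _make_meta(design)
    sample_ids = [m.sample_id for m in meta]
    is_case = np.array([m.group == design.case_label for m in meta])

    class_fold: dict[str, float] = {}
    planted_class_edges = []
    for sub, prod, fold in design.planted_class_effects:
        class_fold[prod] = class_fold.get(prod, 1.0) * fold
        planted_class_edges.append({"reactant": sub, "product": prod, "fold": fold})

    names_all: list[str] = []
    means_all: list[float] = []
    case_mult_all: list[float] = []
    for cls, names in species_by_class.items():
        k = len(names)
        split = rng_struct.dirichlet(np.full(k, 2.0))
        base = design.class_baselines[cls]
        ratio = design.class_effect_ratios.get(cls, 1.0) * class_fold.get(cls, 1.0)
        for name, frac in zip(names, split):
            names_all.append(name)
            means_all.append(base * frac)
            case_mult_all.append(ratio)

    # Chain-level planting: rescale the homo-acyl carrier species so the
    # planted chain's total expected abundance changes by exactly `fold`,
    # leaving every other chain's expectation untouched.
    planted_chain_edges = []
    if design.planted_chain_effects:
        mean_by_name = dict(zip(names_all, means_all))
        idx_by_name = {n: i for i, n in enumerate(names_all)}
        for sub, prod, fold in design.planted_chain_effects:
            total_ab = 0.0
            carrier_ab = 0.0
            carriers = []
            for name, mean in mean_by_name.items():
                species = parse_lipid_name(name, registry)
                if species.annotation_level != "molecular-species":
                    continue
                count = sum(
                    1
                    for ch in species.chains
                    if ch.oxidation == 0 and f"{ch.carbons}:{ch.double_bonds}" == prod
                )
                if count == 0:
                    continue
                total_ab += count * mean
                if all(
                    ch.oxidation == 0
                    and f"{ch.carbons}:{ch.double_bonds}" == prod
                    for ch in species.chains
                ):
                    carrier_ab += count * mean
                    carriers.append(name)
            if carrier_ab <= 0:
                raise InvalidDesignError(
                    f"no homo-acyl carrier species for planted chain {prod}"
                )
            multiplier = 1.0 + (fold - 1.0) * total_ab / carrier_ab
            if multiplier <= 0:
                raise InvalidDesignError(
                    f"planted fold {fold} for chain {prod} is not realisable"
                )
            for name in carriers:
                case_mult_all[idx_by_name[name]] *= multiplier
            planted_chain_edges.append(
                {
                    "reactant": sub,
                    "product": prod,
                    "fold": fold,
                    "carriers": carriers,
                    "carrier_multiplier": multiplier,
                }
            )

    means = np.asarray(means_all)[:, None]
    case_mult = np.asarray(case_mult_all)[:, None]
    group_mult = np.where(is_case[None, :], case_mult, 1.0)
    noise = _noise(rng_noise, design.cv, (len(names_all), len(sample_ids)))
    values = pd.DataFrame(
        means * group_mult * noise, index=names_all, columns=sample_ids
    )

    psy_mult = np.where(is_case, design.psy_ratio, 1.0)
    psy = pd.Series(
        design.psy_control * psy_mult * _noise(rng_psy, design.cv, len(sample_ids)),
        index=sample_ids,
        name="PSY (ng/ug protein)",
    )

    matrix = ConcentrationMatrix(
        values=values, meta=meta, provenance="synthetic"
    )
    truth = GroundTruth(
        class_effect_ratios={
            cls: design.class_effect_ratios.get(cls, 1.0) * class_fold.get(cls, 1.0)
            for cls in design.class_baselines
        },
        planted_class_edges=planted_class_edges,
        planted_chain_edges=planted_chain_edges,
        psy_ratio=design.psy_ratio,
        psy=psy,
        species_means=pd.Series(means_all, index=names_all),
        seed=design.seed,
    )
    return matrix, truth


def generate_feature_table(
    design: SyntheticDesign,
    ismap: ISMap | None = None,
    registry: Mapping[str, LipidClassInfo] | None = None,
    base_is_area: float = 1e5,
) -> SyntheticDataset:
    """Generate a peak-area feature table by inverting the semi-quantification
    formula, so that ``semiquantify``/``quantify_psy`` recover the planted
    concentrations exactly.

    Per-sample global response factors (log-normal, CV 30%) are applied to
    every area to emulate injection variability; the ratio formula cancels
    them.
    """
    if ismap is None:
        ismap = default_is_map()
    if registry is None:
        registry = default_registry()
    matrix, truth = generate_concentrations(design, registry)
    rng = np.random.default_rng([design.seed, 3])
    samples = list(matrix.values.columns)
    meta_by_id = matrix.meta_by_id()

    sample_factor = pd.Series(
        np.exp(rng.normal(0.0, 0.3, len(samples))), index=samples
    )
    is_area = {
        sp: base_is_area * sample_factor for sp in sorted(ismap.is_species)
    }

    rows: dict[str, pd.Series] = {}
    for name in matrix.values.index:
        cls = parse_lipid_name(name, registry).class_code
        entry = ismap.entry(cls)
        spike = ismap.spike(cls)
        conc = matrix.values.loc[name]
        area = pd.Series(
            {
                s: conc[s]
                * meta_by_id[s].protein_amount
                / meta_by_id[s].extract_volume
                / spike
                * is_area[entry.species][s]
                for s in samples
            }
        )
        rows[name] = area

    psy_entry = ismap.entry("PSY")
    psy_spike = ismap.spike("PSY")
    rows[PSY_SPECIES_NAME] = pd.Series(
        {
            s: truth.psy[s]
            * meta_by_id[s].protein_amount
            / meta_by_id[s].extract_volume
            / psy_spike
            * is_area[psy_entry.species][s]
            for s in samples
        }
    )
    for sp, area in is_area.items():
        rows[sp] = area

    areas = pd.DataFrame(rows).T.reindex(columns=samples)
    table = FeatureTable(areas=areas, is_rows=sorted(ismap.is_species))
    return SyntheticDataset(
        table=table, concentrations=matrix, psy=truth.psy, ground_truth=truth
    )
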