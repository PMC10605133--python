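"""Building-block decomposition, conservation, profiles and chain networks."""
import numpy as np
import pandas as pd
import pytest

from lipidkit.chains import (
    build_chain_catalog,
    chain_abundance,
    chain_network,
    chain_network_within_class,
    chain_profiles,
)
from lipidkit.errors import ClassAbsentError
from lipidkit.nomenclature import building_blocks, parse_lipid_name
from lipidkit.quantify import ConcentrationMatrix, SampleMeta
from lipidkit.reactions import CALL_ACTIVATED, CALL_SUPPRESSED, CALL_UNCHANGED
from lipidkit.synthetic import (
    generate_concentrations,
    null_design,
    plant_reaction_effect,
)


def _matrix(values: dict, groups=("WT", "WT", "HOM", "HOM")):
    samples = [f"s{j}" for j in range(len(groups))]
    df = pd.DataFrame(values, index=samples).T
    meta = [SampleMeta(s, g) for s, g in zip(samples, groups)]
    return ConcentrationMatrix(values=df, meta=meta)


def test_incidence_matrix_oracle(rng):
    """Chain abundance equals the hand-built incidence matrix times the
    concentration vectors, on a 10-species toy table."""
    names = [
        "PC 16:0_18:1", "PC 18:1_18:1", "PE 16:0_20:4", "PA 18:1_18:1",
        "CE 18:2", "LPC 18:1", "DG 16:0_16:0", "PS 18:0_18:1",
        "PG 16:1_18:2", "PI 18:0_20:4",
    ]
    conc = rng.uniform(0.1, 3.0, (10, 4))
    m = _matrix({n: conc[i] for i, n in enumerate(names)})
    out = chain_abundance(m)

    chains = sorted(
        {bb for n in names for bb in building_blocks(parse_lipid_name(n))}
    )
    incidence = np.zeros((len(chains), len(names)))
    for j, n in enumerate(names):
        for bb in building_blocks(parse_lipid_name(n)):
            incidence[chains.index(bb), j] += 1.0
    oracle = incidence @ conc
    assert list(out.index) == [f"{c}:{d}" for c, d in chains]
    assert np.allclose(out.to_numpy(), oracle)


def test_conservation_multiplicity_weighted(sn_matrix):
    """Total chain abundance equals the multiplicity-weighted species sum,
    per sample (bases included so every chain is counted)."""
    out = chain_abundance(sn_matrix, include_sphingoid_bases=True)
    expected = pd.Series(0.0, index=sn_matrix.values.columns)
    for name in sn_matrix.values.index:
        sp = parse_lipid_name(name)
        if sp.annotation_level != "molecular-species":
            continue
        expected += len(sp.chains) * sn_matrix.values.loc[name]
    assert np.allclose(out.sum(axis=0), expected)


def test_multiplicity_counts_duplicates():
    m = _matrix({"PA 18:1_18:1": [1.0, 1.0, 1.0, 1.0]})
    with_mult = chain_abundance(m)
    without = chain_abundance(m, multiplicity=False)
    assert np.allclose(with_mult.loc["18:1"], 2.0)
    assert np.allclose(without.loc["18:1"], 1.0)


def test_sphingoid_bases_excluded_by_default():
    m = _matrix({"SM 18:1;O2/16:0": [1.0, 1.0, 1.0, 1.0]})
    out = chain_abundance(m)
    assert list(out.index) == ["16:0"]
    full = chain_abundance(m, include_sphingoid_bases=True)
    assert set(full.index) == {"16:0", "18:1"}


def test_profile_bins():
    m = _matrix({"PC 16:0_18:1": [1.0] * 4, "CE 18:1": [2.0] * 4})
    ab = chain_abundance(m)
    length = chain_profiles(ab, m.meta, axis="length")
    unsat = chain_profiles(ab, m.meta, axis="unsaturation")
    assert list(length.index) == [16, 18]
    assert list(unsat.index) == [0, 1]
    # 18:1 appears in both species: 1 + 2 = 3 per sample
    assert length.loc[18, "mean_WT"] == pytest.approx(3.0)
    assert unsat.loc[0, "mean_WT"] == pytest.approx(1.0)


def test_catalog_edges_only_between_observed_chains():
    cat = build_chain_catalog(["16:0", "18:0", "18:1", "24:6", "22:6"])
    labels = {e.label for e in cat}
    assert labels == {
        "16:0->18:0",   # elongation
        "22:6->24:6",   # elongation
        "18:0->18:1",   # desaturation
        "24:6->22:6",   # beta-oxidation (C>=20 substrate)
    }
    for e in cat:
        assert e.reactant in {"16:0", "18:0", "18:1", "24:6", "22:6"}


def test_catalog_enzyme_annotation():
    cat = build_chain_catalog(["16:0", "16:1", "18:0", "18:1", "18:2", "18:3", "22:0", "24:0", "22:2", "22:3"])
    by_label = {e.label: e for e in cat}
    assert by_label["18:0->18:1"].genes == "SCD1"
    assert by_label["16:0->16:1"].genes == "SCD1"
    assert by_label["18:1->18:2"].genes == "FADS2"
    assert by_label["18:2->18:3"].genes == "FADS2"
    assert by_label["22:2->22:3"].genes == "FADS1"
    assert "ELOVL" in by_label["22:0->24:0"].genes
    assert "ELOVL" in by_label["16:0->18:0"].genes


def test_identical_groups_no_calls():
    m = _matrix({
        "PC 16:0_18:1": [1.0, 1.2, 1.0, 1.2],
        "PC 18:1_18:2": [2.0, 2.2, 2.0, 2.2],
        "CE 16:0": [0.5, 0.4, 0.5, 0.4],
    })
    ab = chain_abundance(m)
    out = chain_network(ab, m.meta)
    assert (out["call"] == CALL_UNCHANGED).all()


def test_planted_desaturation_edge_recovered():
    """18:2 planted x2 in the case group with 18:1 untouched activates the
    18:1 -> 18:2 edge, annotated as delta-6 desaturase."""
    design = plant_reaction_effect(
        null_design("SN", seed=42, n_case=5), ("18:1", "18:2"), 2.0
    )
    matrix, truth = generate_concentrations(design)
    ab = chain_abundance(matrix)
    out = chain_network(ab, matrix.meta)
    assert out.loc["18:1->18:2", "call"] == CALL_ACTIVATED
    assert out.loc["18:1->18:2", "genes"] == "FADS2"


def test_group_swap_flips_chain_calls():
    design = plant_reaction_effect(
        null_design("SN", seed=43, n_case=5), ("18:1", "18:2"), 2.0
    )
    matrix, _ = generate_concentrations(design)
    ab = chain_abundance(matrix)
    fwd = chain_network(ab, matrix.meta, case="HOM", control="WT")
    rev = chain_network(ab, matrix.meta, case="WT", control="HOM")
    assert fwd.loc["18:1->18:2", "call"] == CALL_ACTIVATED
    assert rev.loc["18:1->18:2", "call"] == CALL_SUPPRESSED
    swap = {CALL_ACTIVATED: CALL_SUPPRESSED, CALL_SUPPRESSED: CALL_ACTIVATED,
            CALL_UNCHANGED: CALL_UNCHANGED}
    assert list(rev["call"]) == [swap[c] for c in fwd["call"]]


class TestWithinClass:
    def test_single_chain_class_empty(self):
        m = _matrix({"PA 18:1_18:1": [1.0, 1.1, 0.9, 1.2]})
        out = chain_network_within_class(m, "PA")
        assert out.empty

    def test_absent_class_raises(self):
        m = _matrix({"PA 18:1_18:1": [1.0, 1.1, 0.9, 1.2]})
        with pytest.raises(ClassAbsentError):
            chain_abundance(m, class_code="PC")

    def test_single_class_dataset_matches_global(self):
        m = _matrix({
            "PC 16:0_18:1": [1.0, 1.2, 2.0, 2.2],
            "PC 18:1_18:2": [2.0, 2.2, 1.0, 1.2],
            "PC 16:0_16:0": [0.5, 0.4, 0.5, 0.6],
        })
        within = chain_network_within_class(m, "PC")
        global_ = chain_network(chain_abundance(m), m.meta)
        pd.testing.assert_frame_equal(within, global_)

    def test_planted_within_class_suppression(self):
        """PC-restricted 18:0 -> 18:1 suppression is recovered (SCD1)."""
        rng = np.random.default_rng(9)
        n = 10
        groups = ("WT",) * 5 + ("HOM",) * 5
        noise = lambda: np.exp(rng.normal(0, 0.1, n))  # noqa: E731
        hom = np.array([g == "HOM" for g in groups])
        m = _matrix(
            {
                "PC 18:0_18:0": 1.0 * noise(),
                "PC 18:1_18:1": 2.0 * np.where(hom, 0.4, 1.0) * noise(),
                "PC 16:0_18:0": 1.5 * noise(),
            },
            groups=groups,
        )
        out = chain_network_within_class(m, "PC")
        assert out.loc["18:0->18:1", "call"] == CALL_SUPPRESSED
        assert out.loc["18:0->18:1", "genes"] == "SCD1"
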