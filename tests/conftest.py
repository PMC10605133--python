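import numpy as np
import pytest

from lipidkit.synthetic import default_design, generate_feature_table


@pytest.fixture(scope="session")
def sn_dataset():
    """A default sciatic-nerve-patterned synthetic cohort (5 WT / 4 HOM)."""
    return generate_feature_table(default_design(tissue="SN", seed=7))


@pytest.fixture(scope="session")
def sn_matrix(sn_dataset):
    return sn_dataset.concentrations


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


# A corpus of shorthand names in the dialects the pipeline ingests.
NAME_CORPUS = [
    "CE 20:4",
    "CE 18:2",
    "CE 22:6",
    "Cer 18:1;O2/16:0",
    "CL 18:1_18:1_18:2_16:0",
    "DG 16:0_18:1",
    "PC O-16:1_20:4",
    "PE O-16:1_18:1",
    "PE O-18:1_18:1",
    "PE O-18:2_18:1",
    "PI O-16:0_18:1",
    "HexCer 18:1;O2/24:0",
    "LPC 18:1",
    "LPE 18:0",
    "LPI 20:4",
    "PA 18:0_18:1",
    "PA 18:1_18:1",
    "PA 18:1_22:0",
    "PA 18:0_20:4",
    "PC 16:0_18:1",
    "PC 18:0_18:1",
    "PC 16:0/18:1",
    "PE 18:0_20:4",
    "PG 16:0_18:1",
    "PI 18:0_20:4",
    "PS 18:1_18:1",
    "PS 18:0_18:1",
    "SHexCer 18:1;O2/24:1",
    "SM 18:1;O2/16:0",
    "PSY 18:1;O2",
]


@pytest.fixture(scope="session")
def name_corpus():
    return list(NAME_CORPUS)
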