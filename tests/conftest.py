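"""Shared fixtures: worked-example strings and small molecule corpora."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aoxsom as ax

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


# 2-methylquinazoline -> 4-hydroxy metabolite, as printed (spaces included).
TABLE2_REACTANT_SMILES = "CC1 = NC2 = C(C = CC = C2)C = N1"
TABLE2_REACTION_SMILES = (
    "CC1 = NC2 = C(C = CC = C2)C = N1>>CC3 = NC(O) = C4C = CC = CC4 = N3"
)
TABLE2_MAPPED_REACTION = (
    "[N:1]1 = [CH:2][C:3] = 2[CH:4] = [CH:5][CH:6] = [CH:7][C:8]2[N:9] = [C:10]1[CH3:11]"
    " > > "
    "[CH3:11][C:10] = 1[N:9] = [C:8]2[CH:7] = [CH:6][CH:5] = [CH:4][C:3]2 = "
    "[C:2]([OH:12])[N:1]1"
)
TABLE2_SOM_MAP_NUMBER = 2

TABLE3_REACTANT = "CC(CO)NC1=NC=C2C(N(CC(O)C)C(C(OC3=CC=C(F)C=C3F)=C2)=O)=N1"
TABLE3_PRODUCT = "CC(NC1=NC(O)=C2C(N(C(C(OC3=CC=C(C=C3F)F)=C2)=O)CC(C)O)=N1)CO"
# The printed token rows (single space between tokens; the table's typesetting
# collapses spaces around parentheses, so comparisons normalize whitespace).
TABLE3_REACTANT_TOKENS = (
    "C C ( C O ) N C 1 = N C = C 2 C ( N ( C C ( O ) C ) C ( C ( O C 3 = C C = C "
    "( F ) C = C 3 F ) = C 2 ) = O ) = N 1"
)
TABLE3_PRODUCT_TOKENS = (
    "C C ( N C 1 = N C ( O ) = C 2 C ( N ( C ( C ( O C 3 = C C = C ( C = C 3 F ) "
    "F ) = C 2 ) = O ) C C ( C ) O ) = N 1 ) C O"
)

FIXTURE_SMILES = [
    "c1ccncc1",                # pyridine
    "c1cncnc1",                # pyrimidine
    "Cc1ncc2ccccc2n1",         # 2-methylquinazoline (Table 2 substrate)
    "c1ccc2ncccc2c1",          # quinoline
    "c1ccc2nnccc2c1",          # cinnoline
    "c1ncc2[nH]cnc2n1",        # purine
    "CC(=O)Oc1ccccc1C(=O)O",   # aspirin (no ring N: no candidates)
    "c1ccccc1",                # benzene
    "CC(CO)NC1=NC=C2C(N(CC(O)C)C(C(OC3=CC=C(F)C=C3F)=C2)=O)=N1",
    "C[N+](C)(C)CC(O)O",       # charged, for neutralization paths
]


@pytest.fixture(scope="session")
def fixture_molecules():
    return [ax.standardize_molecule(s, source_id=f"fix-{i}") for i, s in enumerate(FIXTURE_SMILES)]


@pytest.fixture(scope="session")
def pyridine():
    return ax.standardize_molecule("c1ccncc1", source_id="pyridine")


@pytest.fixture(scope="session")
def benzene():
    return ax.standardize_molecule("c1ccccc1", source_id="benzene")


@pytest.fixture(scope="session")
def table2_reaction():
    return ax.parse_mapped_reaction(TABLE2_MAPPED_REACTION)


@pytest.fixture(scope="session")
def synthetic_batch():
    """60 labeled substrates under the bis-N-flanked rule (deterministic)."""
    return ax.generate_substrates(ax.FixtureSpec(seed=11, n_molecules=60))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
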