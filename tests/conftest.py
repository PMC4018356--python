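import numpy as np
import pytest

from fragbayes import chemio, synthdata
from fragbayes.featurize import acf_multilevel

# 50 parseable SMILES spanning rings, charges, heteroatoms, fused systems
SMILES_50 = [
    "C", "CC", "CCO", "CCN", "CCC(=O)O", "c1ccccc1", "c1ccncc1", "c1ccoc1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOC1", "CC(C)C", "CC(C)(C)C", "CC(=O)OC",
    "CC(=O)Nc1ccccc1", "O=C(O)c1ccccc1", "Nc1ccccc1", "Oc1ccccc1",
    "COc1ccccc1", "Clc1ccccc1", "FC(F)(F)c1ccccc1", "c1ccc2ccccc2c1",
    "c1ccc2[nH]ccc2c1", "c1ccc2occc2c1", "O=c1cccc[nH]1", "CN1CCCCC1",
    "O=C1CCCCN1", "C1CN1", "C1CO1", "N#Cc1ccccc1", "CC#N", "CC=C",
    "C/C=C/C", "CC(N)C(=O)O", "NCCO", "OCC(O)CO", "C1CC2CCC1CC2",
    "c1ccc(-c2ccccc2)cc1", "c1ccc(Cc2ccccc2)cc1", "c1ccc(Oc2ccccc2)cc1",
    "CC(=O)[O-]", "[NH4+]", "CC[N+](C)(C)C", "O=S(=O)(O)O", "CS(C)=O",
    "O=[N+]([O-])c1ccccc1", "CCOC(=O)C", "CCOCC", "CCSCC", "O=C(N)C",
]

# 20-molecule fixture for canonicality / permutation properties
FIXTURE_20 = [
    "CCO", "c1ccccc1", "C1CCNCC1", "O=c1cccc[nH]1", "CC(=O)Nc1ccccc1",
    "c1ccc2ccccc2c1", "CN1CCCCC1", "O=C1CCCCN1", "COc1ccncc1",
    "FC(F)(F)c1ccccc1", "CC(C)CC(C)(C)C", "c1ccc(-c2ccccc2)cc1",
    "OCC(O)CO", "N#Cc1ccccc1", "C1CC2CCC1CC2", "Oc1ccc(Cl)cc1",
    "CC(N)C(=O)O", "c1ccc2[nH]ccc2c1", "CCOC(=O)c1ccoc1", "O=S(=O)(N)c1ccccc1",
]


@pytest.fixture(scope="session")
def fixture_graphs():
    return [
        chemio.standardize(chemio.parse_smiles(s, f"FIX{i:02d}"))
        for i, s in enumerate(FIXTURE_20)
    ]


@pytest.fixture(scope="session")
def synthetic_library():
    """The fixed-seed library used by the end-to-end recovery criteria."""
    cfg = synthdata.GeneratorConfig(n_compounds=500, seed=7)
    return synthdata.generate_library(cfg)


@pytest.fixture(scope="session")
def synthetic_featureset_bundle(synthetic_library):
    """Standardized graphs, ACF(<=2) feature sets, labels and the 3:1 split."""
    lib = synthetic_library
    graphs = [chemio.standardize(chemio.parse_smiles(s, r.compound_id)) for s, r in lib]
    featuresets = [acf_multilevel(g, 2) for g in graphs]
    for fs, (_, rec) in zip(featuresets, lib):
        fs.compound_id = rec.compound_id
    labels = np.array([rec.label == "inhibitor" for _, rec in lib])
    split = chemio.split_train_test([rec for _, rec in lib], 0.25, seed=1)
    test_mask = np.array([rec.compound_id in split.test_ids for _, rec in lib])
    return {
        "library": lib,
        "graphs": graphs,
        "featuresets": featuresets,
        "labels": labels,
        "test_mask": test_mask,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
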