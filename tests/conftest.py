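import numpy as np
import pytest

from ember import chem_io, dsc_model, embedding, synthdata

#: a handful of drug-like SMILES used across tests (kinase-inhibitor flavour)
DRUGLIKE_SMILES = [
    "CC(=O)Nc1ccc(O)cc1",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                      # caffeine
    "COc1ccc2ncc(C(=O)N3CCOCC3)c(Nc3ccc(F)cc3)c2c1",   # quinoline amide
    "O=C(Nc1ccc2ncncc2c1)c1cccnc1N1CCNCC1",            # quinazoline amide
    "Nc1ncnc2[nH]cnc12",                               # adenine
    "OCc1ccccc1",
]


@pytest.fixture(scope="session")
def druglike_molecules() -> list[chem_io.Molecule]:
    return [chem_io.Molecule(id=f"D{i}", smiles=chem_io.canonicalize(s))
            for i, s in enumerate(DRUGLIKE_SMILES)]


@pytest.fixture(scope="session")
def benzene() -> chem_io.Molecule:
    return chem_io.Molecule(id="BNZ", smiles=chem_io.canonicalize("c1ccccc1"))


@pytest.fixture(scope="session")
def small_embedded_set():
    """A small embedded synthetic collection shared by model/explain tests."""
    cfg = synthdata.SynthConfig(n_targets=2, n_actives_per_target=25, ratio=5,
                                seed=11)
    mols, labels = synthdata.generate(cfg)
    tensors, failures = embedding.embed_collection(mols)
    assert not failures
    return embedding.stack(tensors), labels, mols


@pytest.fixture(scope="session")
def tiny_trained_model(small_embedded_set):
    """A reduced model trained briefly on the small synthetic set."""
    X, labels, _ = small_embedded_set
    y = labels.astype(float)
    rng = np.random.default_rng(5)
    idx = rng.permutation(len(X))
    n_tr = int(0.8 * len(X))
    n_va = int(0.1 * len(X))
    tr, va = idx[:n_tr], idx[n_tr:n_tr + n_va]
    spec = dsc_model.reduced_model_spec(n_outputs=2)
    model = dsc_model.build_model(spec, seed=7)
    cfg = dsc_model.TrainingConfig(max_epochs=8, patience=3, seed=7)
    dsc_model.train(model, (X[tr], y[tr]), (X[va], y[va]), cfg)
    return model
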