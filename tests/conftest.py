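import pytest

from tasteforest import FixtureSpec, MoleculeRecord, generate_labeled_set, standardize


@pytest.fixture(scope="session")
def tiny_separable_set():
    """10+10 molecules, motif purity 1.0: perfectly separable classes."""
    return generate_labeled_set(
        FixtureSpec(n_per_class=10, motif_purity=1.0, seed=11))


@pytest.fixture(scope="session")
def small_labeled_set():
    """30+30 molecules at purity 0.9: learnable but not trivial."""
    return generate_labeled_set(
        FixtureSpec(n_per_class=30, motif_purity=0.9, seed=23))


@pytest.fixture()
def ethanol():
    return standardize(MoleculeRecord(id="etoh", smiles_raw="CCO"))


@pytest.fixture()
def std_records():
    """A handful of standardized drug-like molecules."""
    smiles = {
        "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
        "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
        "saccharin": "O=C1NS(=O)(=O)c2ccccc21",
        "quinine_core": "c1ccc2ncccc2c1",
        "glucose": "OCC1OC(O)C(O)C(O)C1O",
    }
    return [standardize(MoleculeRecord(id=k, smiles_raw=v))
            for k, v in smiles.items()]
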