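import pytest

from dimerface import (
    ChainMap,
    default_fixture_spec,
    make_toy_annotations,
    make_toy_structure,
    parse_structure,
    toy_catalog_path,
)


@pytest.fixture(scope="session")
def toy_ddi_3did():
    return str(toy_catalog_path("toy_ddi_3did.tsv"))


@pytest.fixture(scope="session")
def toy_ddi_domine():
    return str(toy_catalog_path("toy_ddi_domine.tsv"))


@pytest.fixture(scope="session")
def toy_dmi_path():
    return str(toy_catalog_path("toy_dmi_elm.tsv"))


@pytest.fixture(scope="session")
def toy_classes_path():
    return str(toy_catalog_path("toy_elm_classes.tsv"))


@pytest.fixture()
def fixture_spec():
    return default_fixture_spec(seed=11)


@pytest.fixture()
def toy_world(fixture_spec, tmp_path):
    """A complete planted-interface world: spec, model, annotations, chain map."""
    structure = make_toy_structure(fixture_spec)
    pdb = tmp_path / "model.pdb"
    pdb.write_text(structure.pdb_text)
    model = parse_structure(pdb)
    annotations = make_toy_annotations(fixture_spec)
    chain_map = ChainMap("PROT_A", "A", "PROT_B", "B")
    return {
        "spec": fixture_spec,
        "structure": structure,
        "pdb": pdb,
        "model": model,
        "annotations": annotations,
        "chain_map": chain_map,
    }
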