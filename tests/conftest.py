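import pytest

from inchilink import fixtures, keys, store
from inchilink.inchi_core import parse, serialize

# the four real-chemistry reference InChIs: a carboxylic acid whose sodium
# salt the InChI software deprotonates correctly, and a tetrazole whose
# salt it cannot reprotonate (so parent and salt share no connectivity key)
PABA = "InChI=1S/C7H7NO2/c8-6-3-1-5(2-4-6)7(9)10/h1-4H,8H2,(H,9,10)"
PABA_NA = "InChI=1S/C7H7NO2.Na/c8-6-3-1-5(2-4-6)7(9)10;/h1-4H,8H2,(H,9,10);/q;+1/p-1"
MTZ = "InChI=1S/C2H4N4/c1-2-3-5-6-4-2/h1H3,(H,3,4,5,6)"
MTZ_NA = "InChI=1S/C2H3N4.Na/c1-2-3-5-6-4-2;/h1H3;/q-1;+1"
MTZ_ANION = "InChI=1S/C2H3N4/c1-2-3-5-6-4-2/h1H3/q-1"
NA_CATION = "InChI=1S/Na/q+1"

PRINTED_INCHIS = [PABA, PABA_NA, MTZ, MTZ_NA]


@pytest.fixture(scope="session")
def surrogate():
    return keys.SurrogateKeyProvider()


@pytest.fixture(scope="session")
def toolkit():
    return keys.RDKitKeyProvider()


@pytest.fixture()
def registry(tmp_path, surrogate):
    """An empty registry with one registered source."""
    reg = store.Registry(tmp_path / "registry.sqlite", surrogate)
    reg.add_source(1, "src_one")
    yield reg
    reg.close()


@pytest.fixture()
def acid_salt_registry(registry):
    """The worked-example pair: the acid and its sodium salt."""
    registry.load_source(1, [("ACID", PABA), ("SALT", PABA_NA)])
    return registry


@pytest.fixture()
def family_registry(tmp_path, surrogate):
    """A generated synthetic family loaded into a registry, plus its
    ground-truth manifest."""
    manifest = fixtures.generate(fixtures.FamilySpec(seed=11), tmp_path / "fix")
    reg = store.Registry(tmp_path / "family.sqlite", surrogate)
    for s in manifest["sources"]:
        reg.add_source(s["src_id"], s["name"], keys_only=bool(s["keys_only"]))
        reg.load_source(s["src_id"], store.read_source_file(tmp_path / "fix" / s["file"]))
    yield reg, manifest
    reg.close()
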