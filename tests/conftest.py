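import pytest

from brafclass.aaindex import load_manifest, parse_aaindex1
from brafclass.fixtures import (SyntheticFeatureSpec, ToyStructureSpec,
                                make_aaindex_file, make_feature_table,
                                make_toy_model, make_toy_pdb)
from brafclass.structure import parse_pdb


@pytest.fixture(scope="session")
def toy_spec():
    return ToyStructureSpec(seed=7, helix_spans=[(462, 465)],
                            sheet_spans=[(467, 468)])


@pytest.fixture(scope="session")
def toy_model(toy_spec):
    return make_toy_model(toy_spec)


@pytest.fixture(scope="session")
def toy_pdb(tmp_path_factory, toy_spec):
    path = tmp_path_factory.mktemp("pdb") / "toy.pdb"
    return make_toy_pdb(toy_spec, path)


@pytest.fixture(scope="session")
def parsed_toy(toy_pdb):
    return parse_pdb(toy_pdb)


@pytest.fixture(scope="session")
def scales(tmp_path_factory):
    path = tmp_path_factory.mktemp("aaindex") / "aaindex.txt"
    make_aaindex_file(path, seed=11)
    return parse_aaindex1(path, load_manifest())


@pytest.fixture(scope="session")
def default_table():
    """Synthetic 50-row, 26/24-balanced feature table at default separability."""
    return make_feature_table(SyntheticFeatureSpec(seed=1))


@pytest.fixture(scope="session")
def separable_table():
    """Linearly separable table with a wide inter-class margin."""
    spec = SyntheticFeatureSpec(seed=2, true_coefficients=(2.0, -2.0, 2.0, 2.0),
                                noise_scale=0.0, margin=20.0)
    return make_feature_table(spec)


@pytest.fixture(scope="session")
def chance_table():
    """Labels statistically independent of the features."""
    spec = SyntheticFeatureSpec(seed=3, true_coefficients=(0.0, 0.0, 0.0, 0.0))
    return make_feature_table(spec)
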