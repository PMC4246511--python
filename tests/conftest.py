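import pytest

from protfeat import make_fixture


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One medium synthetic protein with all input files written."""
    out = tmp_path_factory.mktemp("fixture")
    return make_fixture(seed=42, length=60, msa_rows=20, out_dir=out)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_small")
    return make_fixture(seed=7, length=12, msa_rows=5, out_dir=out)
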