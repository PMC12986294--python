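import pytest

from mirquant.simulate import DEFAULT_SEED, PRESETS, make_fixture_suite


@pytest.fixture(scope="session")
def tiny_dir(tmp_path_factory):
    """Self-contained tiny fixture suite (FASTQ through truth JSON)."""
    out = tmp_path_factory.mktemp("fixtures") / "tiny"
    return make_fixture_suite("tiny", out, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def tiny_cfg():
    return PRESETS["tiny"]
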