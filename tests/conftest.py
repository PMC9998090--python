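import pytest

from tmic7.synthetic_data import BundleSpec, make_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default 7-TM bundle with its ground-truth topology."""
    return make_bundle(BundleSpec(seed=1))


@pytest.fixture(scope="session")
def split_bundle():
    """Bundle with planted TM7 split and anchor projection."""
    return make_bundle(BundleSpec(split_seventh=True, anchor_extension=12.0,
                                  seed=2))


@pytest.fixture(scope="session")
def calibration():
    from tmic7.distscore import default_calibration

    return default_calibration()
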