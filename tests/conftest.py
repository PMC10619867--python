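import logging

import pytest

from aquaqc import FixtureSpec, generate_bundle, table4_blank_bundle

logging.getLogger("aquaqc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic bundle plus its ground-truth sidecar."""
    return generate_bundle(FixtureSpec(seed=42))


@pytest.fixture(scope="session")
def blank_bundle():
    """Canned field-blank worked-example bundle (18 blank records)."""
    return table4_blank_bundle()
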