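import hypothesis
import pytest

import plasticome as pc

hypothesis.settings.register_profile(
    "ci", hypothesis.settings(derandomize=True, max_examples=50, deadline=None)
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    """The deterministic small cohort: (table, metadata, tree, taxonomy, truth)."""
    return pc.fixture_small()


@pytest.fixture(scope="session")
def small_table(bundle):
    return bundle[0]


@pytest.fixture(scope="session")
def small_metadata(bundle):
    return bundle[1]


@pytest.fixture(scope="session")
def small_tree(bundle):
    return bundle[2]


@pytest.fixture(scope="session")
def small_taxonomy(bundle):
    return bundle[3]
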