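import pytest

from mitocommon.fixtures import haplogroup_tree
from mitocommon.nomenclature import make_haplotype
from mitocommon.reference import bundled_reference

#: Full-mitogenome background shared by every control-region-identical
#: haplogroup-H sample: the MCH motif plus the universal substitutions.
BASE = "263G 315.1C 750G 1438G 4769G 8860G 15326G 16519C"


@pytest.fixture(scope="session")
def tree():
    return haplogroup_tree()


@pytest.fixture(scope="session")
def reference():
    return bundled_reference()


@pytest.fixture
def mk():
    """Shorthand haplotype builder: mk('id', '263G 315.1C ...')."""

    def build(sample_id, tokens="", base=True, **kwargs):
        text = f"{BASE} {tokens}".strip() if base else tokens
        return make_haplotype(sample_id, text, **kwargs)

    return build
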