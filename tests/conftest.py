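import numpy as np
import pytest

from paleomt.core_io import (Dataset, HVS1Haplotype, Individual,
                             ReferenceSegment, VariantCall)
from paleomt.haplogroup_typing import MotifTree, load_panels


@pytest.fixture(scope="session")
def reference():
    return ReferenceSegment.default()


@pytest.fixture(scope="session")
def tree():
    return MotifTree.default()


@pytest.fixture(scope="session")
def panels():
    return load_panels()


def hap(*tokens, window=(16056, 16390), missing=()):
    """Build a haplotype from '16270T'-style tokens."""
    variants = frozenset(VariantCall(int(t[:-1]), t[-1]) for t in tokens)
    return HVS1Haplotype(variants, window, frozenset(missing))


def ind(ident, *tokens, region="OTHER", period="NEO", haplogroup=None, **kw):
    return Individual(id=ident, region=region, period=period,
                      haplotype=hap(*tokens), haplogroup=haplogroup, **kw)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset(reference):
    """Three sequenced individuals spanning two periods/regions."""
    individuals = [
        ind("a1", "16270T", region="NEI", period="EN"),
        ind("a2", "16224C", "16311C", region="NEI", period="EN"),
        ind("b1", "16069T", "16126C", region="CI", period="MLN"),
    ]
    return Dataset(individuals, reference, (16056, 16390))
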