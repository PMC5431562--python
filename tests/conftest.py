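import dendropy
import pytest
from hypothesis import settings as _hyp_settings

from mitochar import load_fixture

_hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hyp_settings.load_profile("deterministic")


def unrooted_rf(nwk1: str, nwk2: str, taxon_namespace=None) -> int:
    """Robinson–Foulds distance treating both trees as unrooted."""
    tns = taxon_namespace or dendropy.TaxonNamespace()
    trees = []
    for nwk in (nwk1, nwk2):
        if isinstance(nwk, dendropy.Tree):
            t = nwk
        else:
            t = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns)
        t.is_rooted = False
        t.update_bipartitions()
        trees.append(t)
    return dendropy.calculate.treecompare.symmetric_difference(*trees)
from mitochar.synthetic import GenerationPlan, generate_mitogenome


@pytest.fixture(scope="session")
def ckumu():
    return load_fixture("ckumu")


@pytest.fixture(scope="session")
def lmicroptera():
    return load_fixture("lmicroptera")


@pytest.fixture(scope="session")
def syn():
    """One deterministic synthetic mitogenome + its truth manifest."""
    return generate_mitogenome(GenerationPlan(seed=42))


@pytest.fixture(scope="session")
def syn_pair():
    """Two synthetic records with different seeds (for multi-record ops)."""
    r1, _ = generate_mitogenome(GenerationPlan(seed=42))
    r2, _ = generate_mitogenome(GenerationPlan(seed=7))
    return r1, r2
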