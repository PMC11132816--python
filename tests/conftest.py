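import numpy as np
import pytest

from convscan.phylo_io import AA_INDEX, ForegroundSpec, Msa, read_tree
from convscan.simulate import PlantSpec, fixture_foreground, fixture_tree, make_fixture
from convscan.submodel import poisson_model


@pytest.fixture(scope="session")
def poisson():
    return poisson_model()


@pytest.fixture(scope="session")
def poisson6():
    return poisson_model(6)


@pytest.fixture(scope="session")
def quartet_tree():
    return read_tree("((A:0.13,B:0.21):0.17,(C:0.08,D:0.31):0.29);")


@pytest.fixture(scope="session")
def planted_fixture(poisson):
    """The standard 12-taxon planted fixture (seed 1, counts 5/5/5/2/2)."""
    tree, fg, msa, truth = make_fixture(poisson, PlantSpec())
    return tree, fg, msa, truth


@pytest.fixture(scope="session")
def planted_scan(planted_fixture, poisson):
    """Site and indel calls of the full pipeline on the planted fixture."""
    from convscan.indelscan import scan_indels
    from convscan.sitescan import scan_sites

    tree, fg, msa, truth = planted_fixture
    site_calls = scan_sites(msa, tree, poisson, fg, "g1")
    indel_calls = scan_indels(msa, fg, gene="g1")
    return site_calls, indel_calls


def make_pattern(tree, states: dict[str, str]):
    from convscan.asr import SitePattern

    return SitePattern({s: AA_INDEX[states[s]] for s in tree.tip_labels})


def ranked_lists_match(impl, oracle, rtol=1e-9) -> bool:
    """Compare two ranked reconstruction lists, permitting permutations
    within blocks of posterior-tied entries (exchangeable unobserved states
    under equal-rate models produce exact ties; float noise makes the order
    inside a tie block implementation-defined)."""
    if len(impl) != len(oracle):
        return False
    for r, b in zip(impl, oracle):
        if abs(r.posterior - b.posterior) > rtol * max(1e-300, r.posterior, b.posterior):
            return False
    i, n = 0, len(oracle)
    while i < n:
        j = i + 1
        while j < n and (
            abs(oracle[j].posterior - oracle[j - 1].posterior)
            <= rtol * max(oracle[j].posterior, oracle[j - 1].posterior)
            or abs(impl[j].posterior - impl[j - 1].posterior)
            <= rtol * max(impl[j].posterior, impl[j - 1].posterior)
        ):
            j += 1
        if sorted(r.key() for r in impl[i:j]) != sorted(b.key() for b in oracle[i:j]):
            return False
        i = j
    return True
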