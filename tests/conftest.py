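import pytest

from retroplan.feasibility import ClassifierStore
from retroplan.fixtures import expansion_fixture, worked_example_suite
from retroplan.templates import load_default_templates


@pytest.fixture(scope="session")
def library():
    return load_default_templates()


@pytest.fixture(scope="session")
def worked():
    return worked_example_suite()


@pytest.fixture(scope="session")
def chem_target_bbs():
    """Chemistry fixture: target admitting 2-step and 4-step routes."""
    return expansion_fixture()


@pytest.fixture()
def neutral_scores():
    """Classifier store with no classifiers: every template scores 0.5."""
    return ClassifierStore()


def assert_repetition_free(route, net):
    """No compound repeats on any root-to-leaf path of the route tree."""

    def walk(compound, path):
        assert compound not in path, f"{compound} repeats on a path"
        rid = route.tree.get(compound)
        if rid is None:
            return
        for r in net.reactions[rid].reactants:
            walk(r, path | {compound})

    walk(route.root, set())
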