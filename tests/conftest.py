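import pytest

from rinchilib import build_rinchi
from rinchilib import fixtures as fx


@pytest.fixture(scope="session")
def all_molecules():
    """Every fixture molecule as a converted MolRecord."""
    return {name: fx.mol_record(name) for name in fx.MOLECULE_NAMES}


@pytest.fixture(scope="session")
def all_reactions():
    """Every fixture reaction template as a ReactionRecord."""
    return {name: fx.reaction_record(name) for name in fx.REACTIONS}


@pytest.fixture(scope="session")
def all_rinchis(all_reactions):
    """Built identifier per fixture reaction."""
    return {name: build_rinchi(rec)[0] for name, rec in all_reactions.items()}


@pytest.fixture(scope="session")
def small_corpus():
    """A 40-reaction synthetic RDfile with its ground-truth manifest."""
    return fx.make_corpus(fx.CorpusRecipe(n_reactions=40, duplicate_fraction=0.1,
                                          agent_fraction=0.4, seed=11))
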