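import numpy as np
import pytest

from phenolink.ontology import OntologyDAG, propagate, compute_ic
from phenolink.profiles import PhenotypeMatrix
from phenolink.synthetic import SyntheticConfig, make_planted_corpus, make_toy_ontology


@pytest.fixture
def chain_dag():
    """root <- mid <- leaf."""
    return OntologyDAG(
        terms={"root", "mid", "leaf"},
        parents={"root": set(), "mid": {"root"}, "leaf": {"mid"}},
        root="root",
    )


@pytest.fixture
def diamond_dag():
    """root with two children a, b; c below both a and b; d below a only."""
    return OntologyDAG(
        terms={"root", "a", "b", "c", "d"},
        parents={"root": set(), "a": {"root"}, "b": {"root"}, "c": {"a", "b"}, "d": {"a"}},
        root="root",
    )


@pytest.fixture
def toy_corpus(diamond_dag):
    """4 genes: corpus where p(root)=1 and leaf terms have 1 of 4 genes."""
    direct = {"g1": {"c"}, "g2": {"d"}, "g3": {"a"}, "g4": {"b"}}
    return propagate(direct, diamond_dag)


@pytest.fixture
def toy_ic(toy_corpus, diamond_dag):
    return compute_ic(toy_corpus, diamond_dag)


@pytest.fixture(scope="session")
def toy50_dag():
    """~50-term random DAG with multi-parent terms, for closure/mica oracles."""
    return make_toy_ontology(depth=2, branching=6, seed=7, extra_edge_fraction=0.3, prefix="X")


@pytest.fixture
def small_matrix():
    return PhenotypeMatrix(
        genes=["g1", "g2", "g3", "g4"],
        phenotypes=["p1", "p2", "p3"],
        values=np.array([[1, 0, 1], [1, 1, 1], [0, 1, 0], [1, 0, 0]]),
    )


@pytest.fixture(scope="session")
def small_planted():
    """A small planted dataset shared by integration-style tests."""
    cfg = SyntheticConfig(n_genes=120, n_modules=4, n_phenotypes=20, seed=11)
    go = make_toy_ontology(cfg.go_depth, cfg.go_branching, seed=cfg.seed, prefix="GO")
    cmpo = make_toy_ontology(cfg.cmpo_depth, cfg.cmpo_branching, seed=cfg.seed + 1, prefix="CMPO")
    ds = make_planted_corpus(cfg, go, cmpo)
    return cfg, go, cmpo, ds


def brute_force_ancestors(dag: OntologyDAG, term: str) -> frozenset:
    """Independent transitive closure by repeated one-step edge expansion."""
    closure = {term}
    changed = True
    while changed:
        changed = False
        for t in list(closure):
            for parent in dag.parents[t]:
                if parent in dag.terms and parent not in closure:
                    closure.add(parent)
                    changed = True
    return frozenset(closure)
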