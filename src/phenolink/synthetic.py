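"""Seeded synthetic inputs for the whole pipeline.

Generates toy rooted-DAG ontologies, a gene population partitioned into
modules that share both planted functions (deep function-ontology terms) and
planted phenotypes (leaves drawn under module-specific parent terms of the
phenotype ontology), the corresponding binary gene x phenotype matrix with
flip noise and untested-gene zeroing, and interaction pair sets enriched
within modules. Everything is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .benchmark import InteractionSet
from .ontology import AnnotationCorpus, OntologyDAG, propagate
from .profiles import PhenotypeMatrix

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "SyntheticDataset",
    "make_toy_ontology",
    "make_planted_corpus",
    "table1_fixture",
]


@dataclass
class SyntheticConfig:
    """Knobs of the planted-module generator; all probabilities in [0, 1]."""

    n_genes: int = 500
    n_modules: int = 8
    n_phenotypes: int = 48
    noise: float = 0.1  # probability that a matrix 1 flips to 0 and a 0 to 1
    go_depth: int = 3
    go_branching: int = 8
    cmpo_depth: int = 3
    cmpo_branching: int = 8
    within_interaction_prob: float = 0.15
    background_interaction_prob: float = 0.0005
    untested_fraction: float = 0.1
    phenotype_parents_per_module: int = 3
    leaves_per_parent: int = 2
    child_expression_prob: float = 0.6
    go_terms_per_module: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "noise",
            "within_interaction_prob",
            "background_interaction_prob",
            "untested_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_modules > self.n_genes:
            raise ValueError("n_modules cannot exceed n_genes")


@dataclass
class PlantedTruth:
    """Ground truth of the generator, for power and recovery checks."""

    modules: dict[str, int]
    module_go_terms: dict[int, list[str]]
    module_phenotype_parents: dict[int, list[str]]
    informative_phenotypes: set[str]
    module_go_theme: dict[int, str] | None = None
    module_cmpo_theme: dict[int, str] | None = None


@dataclass
class SyntheticDataset:
    go_corpus: AnnotationCorpus
    cmpo_corpus: AnnotationCorpus
    matrix: PhenotypeMatrix
    interactions: InteractionSet
    truth: PlantedTruth = field(repr=False, default=None)

    def __iter__(self):
        return iter((self.go_corpus, self.cmpo_corpus, self.matrix, self.interactions))


def make_toy_ontology(
    depth: int,
    branching: int,
    seed: int = 0,
    extra_edge_fraction: float = 0.1,
    prefix: str = "T",
) -> OntologyDAG:
    """Rooted tree of the given shape plus seeded extra is_a edges.

    Extra edges attach a term to a second parent at a strictly shallower
    level, so the result is always a DAG. Term ids are ``{prefix}:0000001``
    upward, breadth-first from the root.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    counter = 1

    def new_id() -> str:
        nonlocal counter
        tid = f"{prefix}:{counter:07d}"
        counter += 1
        return tid

    root = new_id()
    terms = {root}
    parents: dict[str, set[str]] = {root: set()}
    levels: dict[str, int] = {root: 0}
    frontier = [root]
    for level in range(1, depth + 1):
        nxt = []
        for parent in frontier:
            for _ in range(branching):
                tid = new_id()
                terms.add(tid)
                parents[tid] = {parent}
                levels[tid] = level
                nxt.append(tid)
        frontier = nxt

    candidates = [t for t in sorted(terms) if levels[t] >= 2]
    n_extra = int(round(extra_edge_fraction * len(candidates)))
    if n_extra:
        chosen = rng.choice(len(candidates), size=n_extra, replace=False)
        for i in sorted(chosen.tolist()):
            child = candidates[i]
            shallower = [t for t in sorted(terms) if 0 < levels[t] < levels[child]]
            extra = shallower[int(rng.integers(len(shallower)))]
            parents[child].add(extra)

    names = {t: f"synthetic term {t.split(':')[1].lstrip('0')}" for t in terms}
    return OntologyDAG(terms=terms, parents=parents, root=root, names=names)


def _tree_parent(dag: OntologyDAG, term: str) -> str:
    return min(dag.parents[term])


def term_levels(dag: OntologyDAG) -> dict[str, int]:
    """Longest-path depth of every term from the root (root = 0)."""
    levels: dict[str, int] = {}
    order: list[str] = []
    seen: set[str] = set()

    def visit(t: str) -> None:
        if t in seen:
            return
        seen.add(t)
        for p in dag.parents[t] & dag.terms:
            visit(p)
        order.append(t)

    for t in sorted(dag.terms):
        visit(t)
    for t in order:
        ps = dag.parents[t] & dag.terms
        levels[t] = 1 + max((levels[p] for p in ps), default=-1)
    return levels


def make_planted_corpus(
    cfg: SyntheticConfig, go_dag: OntologyDAG, cmpo_dag: OntologyDAG
) -> SyntheticDataset:
    """Planted-module gene population over the two ontologies.

    Genes are split into ``n_modules`` contiguous blocks. Each module draws
    function-ontology leaf terms (its function signature) and deep
    phenotype-ontology parent terms; each member gene expresses, for each
    parent, one randomly chosen leaf child among the matrix's phenotype
    columns. Matrix entries then flip with the configured noise rate, and a
    fraction of genes is marked untested in a random half of the phenotype
    columns (their 1s zeroed). Positive interactions are sampled within
    modules at the within rate and across modules at the background rate;
    negatives are non-interacting cross-module pairs of matching count.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    modules = {g: i * cfg.n_modules // cfg.n_genes for i, g in enumerate(genes)}

    levels_cmpo = term_levels(cmpo_dag)
    levels_go = term_levels(go_dag)

    # "themes": the root's direct children; each module is planted under one
    # phenotype theme and one function theme so its signature terms are
    # mutually related through a deep common ancestor
    cmpo_themes = sorted(t for t, l in levels_cmpo.items() if l == 1)
    go_themes = sorted(t for t, l in levels_go.items() if l == 1)
    theme_perm = rng.permutation(len(cmpo_themes)).tolist()
    go_theme_perm = rng.permutation(len(go_themes)).tolist()
    module_cmpo_theme = {
        m: cmpo_themes[theme_perm[m % len(cmpo_themes)]] for m in range(cfg.n_modules)
    }
    module_go_theme = {
        m: go_themes[go_theme_perm[m % len(go_themes)]] for m in range(cfg.n_modules)
    }

    # candidate leaf-parents per phenotype theme (enough leaf children)
    cmpo_leaves = sorted(cmpo_dag.leaves())
    by_parent_all: dict[str, list[str]] = {}
    for leaf in cmpo_leaves:
        for p in cmpo_dag.parents[leaf]:
            if levels_cmpo[p] == levels_cmpo[leaf] - 1:
                by_parent_all.setdefault(p, []).append(leaf)
                break
    theme_of_parent = {
        p: next(iter(cmpo_dag.ancestors(p) & set(cmpo_themes)), None) for p in by_parent_all
    }
    parents_by_theme: dict[str, list[str]] = {}
    for p in sorted(by_parent_all):
        if len(by_parent_all[p]) >= cfg.leaves_per_parent and theme_of_parent[p]:
            parents_by_theme.setdefault(theme_of_parent[p], []).append(p)

    # per-module signature parents, drawn inside the module's theme; the
    # parent budget auto-shrinks if the requested column count cannot host it
    budget = cfg.n_phenotypes // (cfg.leaves_per_parent * cfg.n_modules)
    parents_per_module = min(cfg.phenotype_parents_per_module, budget)
    if parents_per_module < 1:
        raise ValueError(
            f"n_phenotypes={cfg.n_phenotypes} cannot host one parent of "
            f"{cfg.leaves_per_parent} leaves per module for {cfg.n_modules} modules"
        )
    used_parents: set[str] = set()
    module_parents: dict[int, list[str]] = {}
    for m in range(cfg.n_modules):
        avail = [p for p in parents_by_theme.get(module_cmpo_theme[m], []) if p not in used_parents]
        if len(avail) < parents_per_module:
            raise ValueError(
                f"phenotype theme {module_cmpo_theme[m]} offers only {len(avail)} "
                f"unused parent terms, need {parents_per_module}"
            )
        picked = sorted(avail[i] for i in rng.choice(len(avail), size=parents_per_module, replace=False))
        used_parents.update(picked)
        module_parents[m] = picked

    # phenotype columns: the signature leaves, padded with unused leaves up to
    # the requested width (padding columns carry noise only)
    phenotypes: list[str] = []
    children_by_parent: dict[str, list[str]] = {}
    for m in range(cfg.n_modules):
        for parent in module_parents[m]:
            kids = by_parent_all[parent]
            picked = sorted(
                kids[i] for i in rng.choice(len(kids), size=cfg.leaves_per_parent, replace=False)
            )
            children_by_parent[parent] = picked
            phenotypes.extend(picked)
    spare = [l for l in cmpo_leaves if l not in set(phenotypes)]
    n_pad = cfg.n_phenotypes - len(phenotypes)
    if n_pad > len(spare):
        raise ValueError("phenotype ontology has too few leaves for the requested width")
    if n_pad > 0:
        phenotypes.extend(sorted(spare[i] for i in rng.choice(len(spare), size=n_pad, replace=False)))
    phenotypes = sorted(phenotypes)
    col_of = {p: j for j, p in enumerate(phenotypes)}

    # function signatures: leaves under the module's function theme
    leaves_by_go_theme: dict[str, list[str]] = {}
    for leaf in sorted(go_dag.leaves()):
        theme = next(iter(go_dag.ancestors(leaf) & set(go_themes)), None)
        if theme:
            leaves_by_go_theme.setdefault(theme, []).append(leaf)
    used_go: set[str] = set()
    module_go: dict[int, list[str]] = {}
    for m in range(cfg.n_modules):
        avail = [t for t in leaves_by_go_theme.get(module_go_theme[m], []) if t not in used_go]
        take = min(cfg.go_terms_per_module, len(avail))
        if take == 0:
            raise ValueError(f"function theme {module_go_theme[m]} has no unused leaves")
        picked = sorted(avail[i] for i in rng.choice(len(avail), size=take, replace=False))
        used_go.update(picked)
        module_go[m] = picked
    go_leaves = sorted(go_dag.leaves())

    # phenotype matrix: each gene expresses every sibling leaf under its
    # signature parents independently (at least one per parent), + flip noise
    values = np.zeros((cfg.n_genes, cfg.n_phenotypes), dtype=np.int8)
    signature_cols: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        cols = []
        for parent in module_parents[modules[g]]:
            children = children_by_parent[parent]
            expressed = [c for c in children if rng.random() < cfg.child_expression_prob]
            if not expressed:
                expressed = [children[int(rng.integers(len(children)))]]
            cols.extend(col_of[c] for c in expressed)
        signature_cols[g] = cols
        values[i, cols] = 1
    if cfg.noise > 0:
        flips = rng.random(values.shape) < cfg.noise
        values = np.where(flips, 1 - values, values).astype(np.int8)

    # untested genes: zero the 1s of a random half of the columns
    n_untested = int(round(cfg.untested_fraction * cfg.n_genes))
    if n_untested:
        untested = rng.choice(cfg.n_genes, size=n_untested, replace=False)
        half = cfg.n_phenotypes // 2
        for i in untested:
            blocked = rng.choice(cfg.n_phenotypes, size=half, replace=False)
            values[i, blocked] = 0
    # keep every gene observable: restore one signature phenotype if wiped out
    for i, g in enumerate(genes):
        if values[i].sum() == 0:
            values[i, signature_cols[g][0]] = 1

    matrix = PhenotypeMatrix(genes=list(genes), phenotypes=list(phenotypes), values=values)

    # annotation corpora; phenotype annotations mirror the matrix exactly
    go_direct: dict[str, set[str]] = {}
    for g in genes:
        sig = module_go[modules[g]]
        kept = {t for t in sig if rng.random() >= cfg.noise}
        if rng.random() < cfg.noise:
            kept.add(go_leaves[int(rng.integers(len(go_leaves)))])
        if not kept:
            kept = {sig[0]}
        go_direct[g] = kept
    go_corpus = propagate(go_direct, go_dag)
    cmpo_corpus = propagate(matrix.to_annotations(), cmpo_dag)

    # interactions: within-module positives, background cross-module positives,
    # cross-module negatives of matching count
    positives: set[tuple[str, str]] = set()
    cross_pairs: list[tuple[str, str]] = []
    for i in range(cfg.n_genes):
        for j in range(i + 1, cfg.n_genes):
            pair = (genes[i], genes[j])
            if modules[genes[i]] == modules[genes[j]]:
                if rng.random() < cfg.within_interaction_prob:
                    positives.add(pair)
            else:
                cross_pairs.append(pair)
    if cfg.background_interaction_prob > 0:
        keep = rng.random(len(cross_pairs)) < cfg.background_interaction_prob
        positives.update(p for p, k in zip(cross_pairs, keep) if k)
    candidates = [p for p in cross_pairs if p not in positives]
    n_neg = min(len(positives), len(candidates))
    neg_idx = rng.choice(len(candidates), size=n_neg, replace=False)
    negatives = {candidates[i] for i in neg_idx.tolist()}
    interactions = InteractionSet(positives=positives, negatives=negatives, universe=set(genes))

    informative = {
        p
        for m in range(cfg.n_modules)
        for parent in module_parents[m]
        for p in children_by_parent[parent]
    }
    truth = PlantedTruth(
        modules=modules,
        module_go_terms=module_go,
        module_phenotype_parents=module_parents,
        informative_phenotypes=informative,
        module_go_theme=module_go_theme,
        module_cmpo_theme=module_cmpo_theme,
    )
    return SyntheticDataset(
        go_corpus=go_corpus,
        cmpo_corpus=cmpo_corpus,
        matrix=matrix,
        interactions=interactions,
        truth=truth,
    )


def table1_fixture() -> dict[str, list[str]]:
    """Packaged screen -> phenotype-identifier table (verbatim fixture)."""
    text = resources.files("phenolink.data").joinpath("table1.tsv").read_text()
    out: dict[str, list[str]] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        screen, pid = line.split("\t")
        out.setdefault(screen, []).append(pid)
    return out
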