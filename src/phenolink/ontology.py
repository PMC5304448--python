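"""Ontology DAG handling: OBO parsing, ancestor closure, annotation propagation,
information content and most-informative common ancestors.

Only ``is_a`` edges are traversed; other relationship types (``part_of`` etc.)
are ignored. Information content is computed on gene counts after ancestor
propagation, in nats, so that ``ic(root) = 0`` whenever every annotated gene
reaches the root.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyDAG",
    "AnnotationCorpus",
    "TermIC",
    "parse_obo",
    "read_gaf",
    "read_annotation_tsv",
    "propagate",
    "compute_ic",
    "mica",
    "write_obo",
]


class OntologyError(ValueError):
    """Structural problem with an ontology (cycle, missing root, ...)."""


@dataclass
class OntologyDAG:
    """Rooted directed acyclic graph of ontology terms with is_a edges.

    ``parents`` maps each term to its direct is_a parents. The designated
    ``root`` may be None for an unrestricted, possibly multi-rooted DAG.
    """

    terms: set[str]
    parents: dict[str, set[str]]
    root: str | None = None
    names: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for term in self.terms:
            self.parents.setdefault(term, set())
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn's algorithm on child->parent edges; leftover nodes lie on a cycle.
        out_degree = {t: len(self.parents[t] & self.terms) for t in self.terms}
        children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps & self.terms:
                children[p].add(child)
        queue = [t for t, d in out_degree.items() if d == 0]
        seen = 0
        while queue:
            node = queue.pop()
            seen += 1
            for child in children[node]:
                out_degree[child] -= 1
                if out_degree[child] == 0:
                    queue.append(child)
        if seen != len(self.terms):
            bad = next(t for t, d in out_degree.items() if d > 0)
            parent = next(iter(self.parents[bad] & self.terms))
            raise OntologyError(
                f"cycle detected in ontology involving edge {bad} -> {parent}"
            )

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """(child, parent) is_a pairs restricted to known terms."""
        return [
            (c, p) for c in sorted(self.terms) for p in sorted(self.parents[c]) if p in self.terms
        ]

    def ancestors(self, term: str, include_self: bool = True) -> frozenset[str]:
        """All terms reachable from ``term`` via is_a edges (cached)."""
        if term not in self.terms:
            raise KeyError(f"unknown term: {term}")
        cached = self._ancestor_cache.get(term)
        if cached is None:
            out: set[str] = {term}
            stack = [term]
            while stack:
                for parent in self.parents[stack.pop()] & self.terms:
                    if parent not in out:
                        out.add(parent)
                        stack.append(parent)
            cached = frozenset(out)
            self._ancestor_cache[term] = cached
        return cached if include_self else frozenset(cached - {term})

    def restrict_to_root(self, root: str) -> "OntologyDAG":
        """Keep exactly the terms from which ``root`` is reachable (root included)."""
        if root not in self.terms:
            raise KeyError(f"root term not found in ontology: {root}")
        keep = {t for t in self.terms if root in self.ancestors(t)}
        parents = {t: self.parents[t] & keep for t in keep}
        return OntologyDAG(
            terms=keep,
            parents=parents,
            root=root,
            names={t: n for t, n in self.names.items() if t in keep},
            obsolete=set(self.obsolete),
        )

    def leaves(self) -> set[str]:
        has_child: set[str] = set()
        for child in self.terms:
            has_child.update(self.parents[child] & self.terms)
        return self.terms - has_child


@dataclass
class AnnotationCorpus:
    """Gene -> term annotations, direct and closed under ancestors."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]
    universe: set[str]
    evidence_filter: tuple[str, ...] = ()

    def genes_annotated_to(self, term: str) -> set[str]:
        return {g for g, ts in self.propagated.items() if term in ts}


@dataclass
class TermIC:
    """Per-term annotation probability and information content (nats)."""

    ic: dict[str, float]
    p: dict[str, float]

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __getitem__(self, term: str) -> float:
        return self.ic[term]


_OBO_TAG_RE = re.compile(r"^(?P<tag>[^:]+):\s*(?P<value>.*)$")


def parse_obo(path: str | Path, root: str | None = None) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyDAG`.

    Only ``[Term]`` stanzas are read, and of those only ``id``, ``name``,
    ``is_a`` and ``is_obsolete``. Obsolete terms are excluded from terms and
    edges. If ``root`` is given the DAG is restricted to the root's
    descendant closure.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"OBO file not found: {path}")

    terms: set[str] = set()
    parents: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    obsolete: set[str] = set()

    current_id: str | None = None
    current_parents: set[str] = set()
    current_name = ""
    current_obsolete = False
    in_term = False

    def flush() -> None:
        nonlocal current_id, current_parents, current_name, current_obsolete
        if current_id is not None:
            if current_obsolete:
                obsolete.add(current_id)
            else:
                terms.add(current_id)
                parents.setdefault(current_id, set()).update(current_parents)
                if current_name:
                    names[current_id] = current_name
        current_id, current_parents, current_name, current_obsolete = None, set(), "", False

    with path.open() as handle:
        for raw in handle:
            line = raw.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                continue
            if not in_term or not line:
                continue
            match = _OBO_TAG_RE.match(line)
            if match is None:
                continue
            tag, value = match.group("tag"), match.group("value")
            value = value.split("!", 1)[0].strip()
            if tag == "id":
                current_id = value
            elif tag == "name":
                current_name = value
            elif tag == "is_a":
                current_parents.add(value)
            elif tag == "is_obsolete" and value.lower() == "true":
                current_obsolete = True
    flush()

    # drop dangling edges to obsolete or unknown terms
    parents = {t: {p for p in ps if p in terms} for t, ps in parents.items()}
    dag = OntologyDAG(terms=terms, parents=parents, names=names, obsolete=obsolete)
    if root is not None:
        dag = dag.restrict_to_root(root)
    return dag


def write_obo(dag: OntologyDAG, path: str | Path) -> None:
    """Write a minimal OBO 1.2 rendering of the DAG (round-trips via parse_obo)."""
    path = Path(path)
    with path.open("w") as handle:
        handle.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            handle.write(f"\n[Term]\nid: {term}\n")
            name = dag.names.get(term)
            if name:
                handle.write(f"name: {name}\n")
            for parent in sorted(dag.parents[term]):
                handle.write(f"is_a: {parent}\n")


DEFAULT_EXCLUDED_EVIDENCE = ("IEA",)


def read_gaf(
    path: str | Path,
    excluded_evidence: Iterable[str] = DEFAULT_EXCLUDED_EVIDENCE,
) -> dict[str, set[str]]:
    """Read gene -> term annotations from a GAF 2.x file.

    Uses column 2 (DB Object ID) as gene, column 5 as term and column 7 as
    evidence code; rows whose evidence code is in ``excluded_evidence``
    (default: IEA) are skipped, as are rows qualified with NOT.
    """
    path = Path(path)
    excluded = set(excluded_evidence)
    direct: dict[str, set[str]] = {}
    n_excluded = 0
    with path.open() as handle:
        for raw in handle:
            if raw.startswith("!") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 7:
                continue
            gene, qualifier, term, evidence = cols[1], cols[3], cols[4], cols[6]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence in excluded:
                n_excluded += 1
                continue
            direct.setdefault(gene, set()).add(term)
    if n_excluded:
        logger.info("excluded %d annotation lines by evidence code %s", n_excluded, sorted(excluded))
    return direct


def read_annotation_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read the minimal two-column dialect ``gene<TAB>term`` (comment lines start with #)."""
    direct: dict[str, set[str]] = {}
    with Path(path).open() as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            direct.setdefault(gene, set()).add(term)
    return direct


def write_annotation_tsv(direct: Mapping[str, set[str]], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for gene in sorted(direct):
            for term in sorted(direct[gene]):
                handle.write(f"{gene}\t{term}\n")


def propagate(
    corpus_direct: Mapping[str, Iterable[str]],
    dag: OntologyDAG,
    evidence_filter: Iterable[str] = (),
) -> AnnotationCorpus:
    """Close each gene's annotations under is_a ancestors.

    Annotated terms absent from the DAG (e.g. cross-branch annotations after
    root restriction) are dropped with a logged warning; genes left without
    any in-DAG annotation are excluded from the universe.
    """
    if not corpus_direct:
        raise ValueError("annotation corpus is empty")
    direct: dict[str, set[str]] = {}
    propagated: dict[str, set[str]] = {}
    n_dropped_terms = 0
    for gene, terms in corpus_direct.items():
        in_dag = {t for t in terms if t in dag.terms}
        n_dropped_terms += len(set(terms)) - len(in_dag)
        if not in_dag:
            continue
        direct[gene] = in_dag
        closure: set[str] = set()
        for term in in_dag:
            closure |= dag.ancestors(term)
        propagated[gene] = closure
    if n_dropped_terms:
        logger.warning("dropped %d annotations to terms outside the DAG", n_dropped_terms)
    if not direct:
        raise ValueError("no annotation maps to a term of the DAG")
    return AnnotationCorpus(
        direct=direct,
        propagated=propagated,
        universe=set(direct),
        evidence_filter=tuple(evidence_filter),
    )


def compute_ic(corpus: AnnotationCorpus, dag: OntologyDAG) -> TermIC:
    """Annotation-probability information content from propagated gene counts.

    p(t) = (#genes whose propagated annotations contain t) / |universe|;
    ic(t) = -log p(t). Terms annotating no gene get no IC entry.
    """
    if not corpus.universe:
        raise ValueError("annotation corpus has an empty universe")
    counts: dict[str, int] = {}
    for terms in corpus.propagated.values():
        for term in terms:
            if term in dag.terms:
                counts[term] = counts.get(term, 0) + 1
    total = len(corpus.universe)
    p = {t: c / total for t, c in counts.items()}
    ic = {t: -math.log(pt) for t, pt in p.items()}
    return TermIC(ic=ic, p=p)


def mica(t1: str, t2: str, dag: OntologyDAG, ic: TermIC) -> tuple[str, float]:
    """Most informative common ancestor-or-self of two terms.

    Ties are broken by the lexicographically smallest term id so the result
    is deterministic.
    """
    for t in (t1, t2):
        if t not in dag.terms:
            raise KeyError(f"term not in DAG: {t}")
        if t not in ic:
            raise KeyError(f"term has no information content: {t}")
    common = dag.ancestors(t1) & dag.ancestors(t2)
    common = {t for t in common if t in ic}
    if not common:
        raise LookupError(f"terms {t1} and {t2} share no common ancestor with IC")
    best = min(common, key=lambda t: (-ic.ic[t], t))
    return best, ic.ic[best]
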