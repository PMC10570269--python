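"""Phenotype ontology: a rooted DAG of terms with parent/ancestor queries.

The ontology plays two roles in the simulator: phenotype *obfuscation*
replaces a specific term with one of its less precise parents, and the
semantic-similarity rankers score term sets through their shared ancestor
closures.  Both only need parent edges, so the ontology is held as a plain
``term -> set(parents)`` map with memoised transitive closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set

import networkx as nx
import obonet

__all__ = ["Term", "Ontology", "load_ontology"]


@dataclass(frozen=True)
class Term:
    """A single ontology term (CURIE-style accession plus label)."""

    id: str
    name: str = ""


class OntologyError(ValueError):
    pass


class Ontology:
    """Rooted DAG of phenotype terms.

    Parameters
    ----------
    parents
        Map from term id to the ids of its direct parents.  Exactly one
        term (the root) must have no parents, and every term must reach
        the root through parent edges.
    names
        Optional map from term id to human-readable label.
    """

    def __init__(self, parents: Mapping[str, Iterable[str]], names: Optional[Mapping[str, str]] = None):
        self._parents: Dict[str, FrozenSet[str]] = {t: frozenset(ps) for t, ps in parents.items()}
        # referenced parents must themselves be terms
        for t, ps in self._parents.items():
            for p in ps:
                if p not in self._parents:
                    raise OntologyError(f"term {t!r} has unknown parent {p!r}")
        self._names: Dict[str, str] = dict(names or {})
        roots = [t for t, ps in self._parents.items() if not ps]
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root term, found {len(roots)}: {sorted(roots)[:5]}")
        self.root: str = roots[0]
        self._check_dag()
        self._anc_cache: Dict[str, FrozenSet[str]] = {}
        self._children: Optional[Dict[str, Set[str]]] = None

    def _check_dag(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._parents)
        for t, ps in self._parents.items():
            g.add_edges_from((t, p) for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise OntologyError("parent graph is not a DAG")
        # every term must reach the root
        reach = nx.ancestors(g, self.root) | {self.root}
        orphans = set(self._parents) - reach
        if orphans:
            raise OntologyError(f"{len(orphans)} terms cannot reach the root, e.g. {sorted(orphans)[:5]}")

    # -- queries ---------------------------------------------------------
    def __contains__(self, term: str) -> bool:
        return term in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    @property
    def terms(self) -> FrozenSet[str]:
        return frozenset(self._parents)

    def name(self, term: str) -> str:
        return self._names.get(term, "")

    def parents(self, term: str) -> FrozenSet[str]:
        try:
            return self._parents[term]
        except KeyError:
            raise KeyError(f"unknown ontology term: {term!r}") from None

    def children(self, term: str) -> FrozenSet[str]:
        if self._children is None:
            ch: Dict[str, Set[str]] = {t: set() for t in self._parents}
            for t, ps in self._parents.items():
                for p in ps:
                    ch[p].add(t)
            self._children = ch
        return frozenset(self._children[term])

    def ancestors(self, term: str, include_self: bool = True) -> FrozenSet[str]:
        """Reflexive-transitive closure over parent edges.

        With ``include_self=False`` the term itself is excluded (the root's
        strict ancestor set is empty).
        """
        closure = self._closure(term)
        return closure if include_self else closure - {term}

    def _closure(self, term: str) -> FrozenSet[str]:
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        ps = self.parents(term)  # raises on unknown term
        out: Set[str] = {term}
        for p in ps:
            out |= self._closure(p)
        result = frozenset(out)
        self._anc_cache[term] = result
        return result

    def closure_of_set(self, terms: Iterable[str]) -> FrozenSet[str]:
        """Union of ancestor closures of a term set (terms included)."""
        out: Set[str] = set()
        for t in terms:
            out |= self._closure(t)
        return frozenset(out)

    def descendants(self, term: str, include_self: bool = True) -> FrozenSet[str]:
        """All terms whose ancestor closure contains ``term``."""
        if term not in self._parents:
            raise KeyError(f"unknown ontology term: {term!r}")
        out = {t for t in self._parents if term in self._closure(t)}
        return frozenset(out) if include_self else frozenset(out - {term})


def load_ontology(path: str, root: Optional[str] = None, drop_obsolete: bool = True) -> Ontology:
    """Read an OBO 1.2/1.4 file into an :class:`Ontology`.

    Obsolete terms are dropped (or remapped if they carry ``replaced_by``
    and ``drop_obsolete`` is false; obonet already excludes obsolete stanzas
    by default).  ``root`` optionally names the expected root term; loading
    fails if the file's single parentless term differs.
    """
    graph = obonet.read_obo(path)
    parents: Dict[str, Set[str]] = {}
    names: Dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        names[node] = data.get("name", "")
        parents[node] = set()
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    onto = Ontology(parents, names)
    if root is not None and onto.root != root:
        raise OntologyError(f"expected root {root!r}, found {onto.root!r}")
    return onto
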