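"""Core domain containers: the binary association matrix and the disease ontology.

The association matrix ``Y`` is a dense binary ``p x q`` array whose rows are
lncRNAs and columns are diseases. Row ``i`` of ``Y`` is the interaction
profile ``IP(l_i)`` of lncRNA ``i``; column ``j`` is the interaction profile
``IP(d_j)`` of disease ``j``. The disease ontology is a rooted DAG of
parent -> child edges (MeSH-like), used for semantic similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .exceptions import IdentifierError, OntologyError

__all__ = ["AssociationMatrix", "DiseaseOntology"]


@dataclass(frozen=True)
class AssociationMatrix:
    """Known lncRNA-disease associations with identifier registries.

    Parameters
    ----------
    values : ndarray of shape (p, q)
        Binary matrix; ``values[i, j] == 1`` iff lncRNA ``i`` is known to be
        associated with disease ``j``.
    lncrna_ids : sequence of str, length p
        Ordered unique lncRNA identifiers (row labels).
    disease_ids : sequence of str, length q
        Ordered unique disease identifiers (column labels).
    """

    values: np.ndarray
    lncrna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "lncrna_ids", tuple(self.lncrna_ids))
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        if values.ndim != 2:
            raise ValueError(f"association matrix must be 2-D, got {values.ndim}-D")
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be exactly 0 or 1")
        p, q = values.shape
        if len(self.lncrna_ids) != p:
            raise IdentifierError(
                f"{len(self.lncrna_ids)} lncRNA ids for {p} matrix rows"
            )
        if len(self.disease_ids) != q:
            raise IdentifierError(
                f"{len(self.disease_ids)} disease ids for {q} matrix columns"
            )
        if len(set(self.lncrna_ids)) != p:
            raise IdentifierError("duplicate lncRNA identifiers")
        if len(set(self.disease_ids)) != q:
            raise IdentifierError("duplicate disease identifiers")

    @property
    def n_lncrnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        lncrna_ids: Sequence[str] | None = None,
        disease_ids: Sequence[str] | None = None,
    ) -> "AssociationMatrix":
        """Build a matrix from (lncrna_id, disease_id) pairs.

        Identifier order is first-appearance order unless explicit registries
        are given (which may include entities with no association).
        Duplicate pairs are merged.
        """
        pairs = list(pairs)
        if lncrna_ids is None:
            lncrna_ids = list(dict.fromkeys(l for l, _ in pairs))
        if disease_ids is None:
            disease_ids = list(dict.fromkeys(d for _, d in pairs))
        li = {name: i for i, name in enumerate(lncrna_ids)}
        di = {name: j for j, name in enumerate(disease_ids)}
        values = np.zeros((len(lncrna_ids), len(disease_ids)))
        for l, d in pairs:
            if l not in li:
                raise IdentifierError(f"unknown lncRNA identifier: {l!r}")
            if d not in di:
                raise IdentifierError(f"unknown disease identifier: {d!r}")
            values[li[l], di[d]] = 1.0
        return cls(values, tuple(lncrna_ids), tuple(disease_ids))

    def with_values(self, values: np.ndarray) -> "AssociationMatrix":
        """Return a copy sharing the registries but holding new values."""
        return AssociationMatrix(values, self.lncrna_ids, self.disease_ids)

    def pairs(self) -> list[tuple[str, str]]:
        """Known associations as (lncrna_id, disease_id) pairs, row-major."""
        rows, cols = np.nonzero(self.values)
        return [(self.lncrna_ids[i], self.disease_ids[j]) for i, j in zip(rows, cols)]


@dataclass(frozen=True)
class DiseaseOntology:
    """A rooted DAG over disease terms.

    ``edges`` are directed parent -> child pairs. Terms with no parent are
    roots; isolated terms (no edges at all) are allowed and act as their own
    root. Acyclicity is validated at construction.
    """

    terms: frozenset[str]
    edges: tuple[tuple[str, str], ...]
    _parents: Mapping[str, tuple[str, ...]] = field(repr=False, compare=False, default=None)
    _children: Mapping[str, tuple[str, ...]] = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))
        object.__setattr__(self, "edges", tuple((p, c) for p, c in self.edges))
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for parent, child in self.edges:
            if parent == child:
                raise OntologyError(f"self-edge on term {parent!r}")
            if parent not in self.terms or child not in self.terms:
                raise IdentifierError(
                    f"edge ({parent!r}, {child!r}) references a term outside the ontology"
                )
            graph.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(f"ontology contains a cycle: {cycle}")
        parents: dict[str, tuple[str, ...]] = {
            t: tuple(sorted(graph.predecessors(t))) for t in self.terms
        }
        children: dict[str, tuple[str, ...]] = {
            t: tuple(sorted(graph.successors(t))) for t in self.terms
        }
        object.__setattr__(self, "_parents", parents)
        object.__setattr__(self, "_children", children)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_terms: Iterable[str] = ()
    ) -> "DiseaseOntology":
        edges = tuple(edges)
        terms = {t for e in edges for t in e} | set(extra_terms)
        return cls(frozenset(terms), edges)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def parents(self, term: str) -> tuple[str, ...]:
        self._check(term)
        return self._parents[term]

    def children(self, term: str) -> tuple[str, ...]:
        self._check(term)
        return self._children[term]

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including ``term`` itself (the set T(d))."""
        self._check(term)
        seen = {term}
        frontier = [term]
        while frontier:
            node = frontier.pop()
            for parent in self._parents[node]:
                if parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
        return frozenset(seen)

    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self._parents[t])

    def _check(self, term: str) -> None:
        if term not in self.terms:
            raise IdentifierError(f"unknown disease term: {term!r}")
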