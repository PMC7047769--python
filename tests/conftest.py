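"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (explicit double loops, exhaustive
support-set enumeration, all-pairs counting) so they stay independent of
the vectorized code paths they validate.
"""

from __future__ import annotations

import numpy as np
import pytest


from mvclda.datatypes import AssociationMatrix, DiseaseOntology
from mvclda.synthetic import SyntheticConfig, generate_associations, generate_ontology

# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture()
def chain_ontology() -> DiseaseOntology:
    """root -> a -> d."""
    return DiseaseOntology.from_edges([("root", "a"), ("a", "d")])


@pytest.fixture()
def diamond_ontology() -> DiseaseOntology:
    """root -> {a, b}; a -> d; b -> d."""
    return DiseaseOntology.from_edges(
        [("root", "a"), ("root", "b"), ("a", "d"), ("b", "d")]
    )


@pytest.fixture()
def sibling_ontology() -> DiseaseOntology:
    """One root with two leaf children d1, d2."""
    return DiseaseOntology.from_edges([("root", "d1"), ("root", "d2")])


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A small dense planted problem where recovery is quick to evaluate."""
    return SyntheticConfig(
        n_lncrnas=30, n_diseases=24, n_blocks=3,
        density_in=0.5, density_out=0.02, seed=1,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    ontology = generate_ontology(small_config)
    assoc, labels = generate_associations(small_config)
    return assoc, ontology, labels


# ---------------------------------------------------------------------------
# oracle helpers (imported by test modules via conftest namespace)


def random_dag(rng: np.random.Generator, n_terms: int = 10, p_edge: float = 0.3):
    """Random DAG over t0..t{n-1}: edge ti -> tj only for i < j (acyclic)."""
    terms = [f"t{i}" for i in range(n_terms)]
    edges = [
        (terms[i], terms[j])
        for i in range(n_terms)
        for j in range(i + 1, n_terms)
        if rng.random() < p_edge
    ]
    return DiseaseOntology(frozenset(terms), tuple(edges)), terms


def random_association(rng: np.random.Generator, p: int = 8, q: int = 6, density=0.35):
    values = (rng.random((p, q)) < density).astype(float)
    return AssociationMatrix(
        values, tuple(f"l{i}" for i in range(p)), tuple(f"d{j}" for j in range(q))
    )


def random_similarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric unit-diagonal matrix with entries in [0, 1]."""
    raw = rng.random((n, n))
    sym = (raw + raw.T) / 2.0
    np.fill_diagonal(sym, 1.0)
    return sym


def oracle_semantic_contributions(ontology: DiseaseOntology, d: str) -> dict[str, float]:
    """Direct recursive evaluation of ancestor contributions."""
    anc = ontology.ancestors(d)

    def contrib(t: str) -> float:
        if t == d:
            return 1.0
        return max(0.5 * contrib(c) for c in ontology.children(t) if c in anc)

    return {t: contrib(t) for t in anc}


def oracle_semantic_similarity(ontology: DiseaseOntology, d1: str, d2: str) -> float:
    c1 = oracle_semantic_contributions(ontology, d1)
    c2 = oracle_semantic_contributions(ontology, d2)
    shared = set(c1) & set(c2)
    if not shared:
        return 0.0
    return sum(c1[t] + c2[t] for t in shared) / (sum(c1.values()) + sum(c2.values()))


def oracle_functional_similarity(Y: np.ndarray, S: np.ndarray, i: int, j: int) -> float:
    """Explicit best-match average over the two disease sets."""
    Di = [d for d in range(Y.shape[1]) if Y[i, d] == 1]
    Dj = [d for d in range(Y.shape[1]) if Y[j, d] == 1]
    if i == j:
        return 1.0
    if not Di or not Dj:
        return 0.0
    total = sum(max(S[d, d1] for d1 in Di) for d in Dj)
    total += sum(max(S[d, d1] for d1 in Dj) for d in Di)
    return total / (len(Di) + len(Dj))


def oracle_simplex_project(v: np.ndarray) -> np.ndarray:
    """Exact simplex-QP solve by enumerating every candidate support set.

    For a fixed support A the equality-constrained minimizer is
    x_i = v_i - theta with theta = (sum_A v_i - 1)/|A|; the KKT conditions
    require x >= 0 on A and v_i - theta <= 0 off A. Exactly one support
    satisfies both (up to degenerate ties), and enumeration finds it.
    """
    v = np.asarray(v, dtype=float)
    n = len(v)
    best, best_obj = None, np.inf
    for mask in range(1, 2**n):
        A = [i for i in range(n) if mask >> i & 1]
        theta = (v[A].sum() - 1.0) / len(A)
        x = np.zeros(n)
        x[A] = v[A] - theta
        if x[A].min() < -1e-12:
            continue
        off = [i for i in range(n) if i not in A]
        if off and (v[off] - theta).max() > 1e-12:
            continue
        obj = np.sum((x - v) ** 2)
        if obj < best_obj:
            best, best_obj = x, obj
    assert best is not None
    return best


def oracle_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force all-pairs concordance count with midrank ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))
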