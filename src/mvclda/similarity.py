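"""Similarity views for diseases and lncRNAs.

Three disease-side views and three lncRNA-side views are built from a known
association matrix Y and a disease ontology:

* disease semantic similarity — ontology-DAG similarity where each ancestor
  of a disease contributes a semantic value decaying by a factor 0.5 per
  generation, and shared-ancestor contributions are normalized by the total
  semantic values of the two diseases;
* lncRNA functional similarity — best-match averaging of semantic
  similarities between the two lncRNAs' associated disease sets;
* Gaussian interaction profile (GIP) kernel similarity — Gaussian kernel
  over rows (lncRNAs) or columns (diseases) of Y, bandwidth normalized by
  the mean squared profile norm;
* cosine similarity over the same interaction profiles.

All views are symmetric, unit-diagonal and entrywise in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .datatypes import AssociationMatrix, DiseaseOntology
from .exceptions import ConfigError, IdentifierError, NumericalError

__all__ = [
    "SimilarityView",
    "ViewSet",
    "semantic_contributions",
    "semantic_value",
    "disease_semantic_similarity",
    "lncrna_functional_similarity",
    "gip_similarity",
    "cosine_similarity_matrix",
    "build_views",
]

_SIDES = ("lncrna", "disease")


@dataclass(frozen=True)
class SimilarityView:
    """A square similarity matrix over one side of the bipartite problem.

    Invariants (checked on construction): symmetric to 1e-10, entries in
    [0, 1], unit diagonal.
    """

    values: np.ndarray
    side: str
    name: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.side not in _SIDES:
            raise ConfigError(f"side must be one of {_SIDES}, got {self.side!r}")
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"similarity view must be square, got shape {values.shape}")
        if not np.allclose(values, values.T, atol=1e-10, rtol=0.0):
            raise ValueError(f"{self.name} view is not symmetric")
        if values.min() < -1e-12 or values.max() > 1.0 + 1e-12:
            raise ValueError(f"{self.name} view has entries outside [0, 1]")
        if not np.allclose(np.diag(values), 1.0, atol=1e-10):
            raise ValueError(f"{self.name} view diagonal is not 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ViewSet:
    """Ordered disease-side (q x q) and lncRNA-side (p x p) similarity views."""

    disease_views: tuple[SimilarityView, ...]
    lncrna_views: tuple[SimilarityView, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "disease_views", tuple(self.disease_views))
        object.__setattr__(self, "lncrna_views", tuple(self.lncrna_views))
        if not self.disease_views or not self.lncrna_views:
            raise ConfigError("need at least one view per side")
        for views, side in ((self.disease_views, "disease"), (self.lncrna_views, "lncrna")):
            sizes = {v.n for v in views}
            if len(sizes) != 1:
                raise ValueError(f"inconsistent {side} view sizes: {sorted(sizes)}")
            if any(v.side != side for v in views):
                raise ValueError(f"view with wrong side among {side} views")

    @property
    def n_disease_views(self) -> int:
        return len(self.disease_views)

    @property
    def n_lncrna_views(self) -> int:
        return len(self.lncrna_views)

    def disease_arrays(self) -> list[np.ndarray]:
        return [v.values for v in self.disease_views]

    def lncrna_arrays(self) -> list[np.ndarray]:
        return [v.values for v in self.lncrna_views]


def semantic_contributions(ontology: DiseaseOntology, disease: str) -> dict[str, float]:
    """Semantic contribution D_d(t) of every ancestor t of ``disease``.

    The disease itself contributes 1; any other ancestor t contributes
    0.5 times the largest contribution among its children that are
    themselves ancestors of ``disease``.
    """
    ancestors = ontology.ancestors(disease)
    memo: dict[str, float] = {disease: 1.0}

    def contrib(term: str) -> float:
        if term in memo:
            return memo[term]
        value = 0.5 * max(
            contrib(child) for child in ontology.children(term) if child in ancestors
        )
        memo[term] = value
        return value

    for term in ancestors:
        contrib(term)
    return memo


def semantic_value(ontology: DiseaseOntology, disease: str) -> float:
    """Overall semantic value D(d): the sum of all ancestor contributions."""
    return float(sum(semantic_contributions(ontology, disease).values()))


def disease_semantic_similarity(
    ontology: DiseaseOntology,
    diseases: Sequence[str],
    permissive: bool = False,
) -> SimilarityView:
    """Pairwise semantic similarity over an ordered list of disease terms.

    For diseases i, j with ancestor contribution maps D_i, D_j, the
    similarity is the sum of D_i(t) + D_j(t) over shared ancestors t,
    divided by D(i) + D(j). The diagonal is 1.

    With ``permissive=True``, terms absent from the ontology get an all-zero
    similarity row/column (diagonal 1) instead of raising.
    """
    diseases = list(diseases)
    q = len(diseases)
    contribs: list[dict[str, float] | None] = []
    for d in diseases:
        if d not in ontology:
            if not permissive:
                raise IdentifierError(f"disease term {d!r} is not in the ontology")
            contribs.append(None)
        else:
            contribs.append(semantic_contributions(ontology, d))
    totals = [sum(c.values()) if c is not None else 0.0 for c in contribs]

    values = np.eye(q)
    for i in range(q):
        ci = contribs[i]
        if ci is None:
            continue
        keys_i = set(ci)
        for j in range(i + 1, q):
            cj = contribs[j]
            if cj is None:
                continue
            shared = keys_i & cj.keys()
            if not shared:
                continue
            s = sum(ci[t] + cj[t] for t in shared) / (totals[i] + totals[j])
            values[i, j] = values[j, i] = s
    return SimilarityView(values, side="disease", name="semantic")


def lncrna_functional_similarity(
    assoc: AssociationMatrix, semantic: SimilarityView
) -> SimilarityView:
    """Functional similarity between lncRNAs via their associated diseases.

    For lncRNAs i, j with disease sets D(l_i), D(l_j) of sizes m and n,
    LFS(i, j) averages the best-match semantic similarity of each disease in
    one set against the other set, summed both ways and divided by m + n.
    An lncRNA with an empty disease set (possible inside CV folds) gets zero
    off-diagonal similarity; the diagonal is always 1.
    """
    if semantic.n != assoc.n_diseases:
        raise ValueError(
            f"semantic view is {semantic.n}x{semantic.n} but Y has "
            f"{assoc.n_diseases} diseases"
        )
    S = semantic.values
    p = assoc.n_lncrnas
    disease_sets = [np.nonzero(assoc.values[i])[0] for i in range(p)]
    values = np.eye(p)
    for i in range(p):
        di = disease_sets[i]
        if di.size == 0:
            continue
        for j in range(i + 1, p):
            dj = disease_sets[j]
            if dj.size == 0:
                continue
            sub = S[np.ix_(di, dj)]
            # best match of each d in D(l_j) against D(l_i), and vice versa
            lfs = (sub.max(axis=0).sum() + sub.max(axis=1).sum()) / (di.size + dj.size)
            values[i, j] = values[j, i] = lfs
    return SimilarityView(values, side="lncrna", name="functional")


def _profiles(assoc: AssociationMatrix, side: str) -> np.ndarray:
    if side == "lncrna":
        return assoc.values
    if side == "disease":
        return assoc.values.T
    raise ConfigError(f"side must be one of {_SIDES}, got {side!r}")


def gip_similarity(
    assoc: AssociationMatrix, side: str, bandwidth_scale: float = 1.0
) -> SimilarityView:
    """Gaussian interaction profile kernel similarity.

    K(i, j) = exp(-beta * ||IP(i) - IP(j)||^2) with the bandwidth
    beta = bandwidth_scale / mean(||IP(i)||^2) taken over all profiles on
    the chosen side. Profiles are rows of Y for lncRNAs, columns for
    diseases.
    """
    if bandwidth_scale <= 0:
        raise ConfigError(f"bandwidth_scale must be positive, got {bandwidth_scale}")
    profiles = _profiles(assoc, side)
    mean_sq_norm = float(np.mean((profiles**2).sum(axis=1)))
    if mean_sq_norm == 0.0:
        raise NumericalError(
            f"all {side} interaction profiles are zero; GIP bandwidth is undefined"
        )
    beta = bandwidth_scale / mean_sq_norm
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-beta * sq_dists)
    return SimilarityView(values, side=side, name="gip")


def cosine_similarity_matrix(assoc: AssociationMatrix, side: str) -> SimilarityView:
    """Cosine similarity between interaction profiles.

    Profiles with zero norm get zero off-diagonal similarity (diagonal 1),
    keeping the view a valid similarity matrix.
    """
    profiles = _profiles(assoc, side)
    norms = np.linalg.norm(profiles, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    values = (profiles @ profiles.T) / np.outer(safe, safe)
    values[norms == 0, :] = 0.0
    values[:, norms == 0] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    return SimilarityView(values, side=side, name="cosine")


def build_views(
    assoc: AssociationMatrix,
    ontology: DiseaseOntology | None = None,
    bandwidth_scale: float = 1.0,
    permissive: bool = False,
) -> ViewSet:
    """Assemble the full view set from one association matrix.

    With an ontology: disease views are [semantic, gip, cosine] and lncRNA
    views are [functional, gip, cosine]. Without one, both sides fall back
    to [gip, cosine] and a warning is emitted. All Y-derived views are
    computed from the matrix passed in, so cross-validation folds can
    rebuild views from a training matrix without leakage.
    """
    if ontology is not None:
        semantic = disease_semantic_similarity(
            ontology, assoc.disease_ids, permissive=permissive
        )
        disease_views = [
            semantic,
            gip_similarity(assoc, "disease", bandwidth_scale),
            cosine_similarity_matrix(assoc, "disease"),
        ]
        lncrna_views = [
            lncrna_functional_similarity(assoc, semantic),
            gip_similarity(assoc, "lncrna", bandwidth_scale),
            cosine_similarity_matrix(assoc, "lncrna"),
        ]
    else:
        warnings.warn(
            "no ontology provided; building GIP and cosine views only",
            UserWarning,
            stacklevel=2,
        )
        disease_views = [
            gip_similarity(assoc, "disease", bandwidth_scale),
            cosine_similarity_matrix(assoc, "disease"),
        ]
        lncrna_views = [
            gip_similarity(assoc, "lncrna", bandwidth_scale),
            cosine_similarity_matrix(assoc, "lncrna"),
        ]
    return ViewSet(tuple(disease_views), tuple(lncrna_views))
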