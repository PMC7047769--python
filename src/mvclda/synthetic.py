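"""Synthetic ontologies and association matrices with planted structure.

The generator emulates the regime of curated lncRNA-disease catalogs:
a few hundred lncRNAs and diseases, a few hundred verified associations
(density well under 1%), and a MeSH-like rooted DAG over the disease terms.
Signal is planted as block (cluster) structure: lncRNAs and diseases are
assigned to blocks round-robin, matched pairs associate with probability
``density_in`` and unmatched pairs with ``density_out``, and same-block
disease terms share a deep common ancestor in the generated DAG while
cross-block terms share only the global root.

The defaults reproduce the scale of the largest curated dataset the method
is aimed at: 285 lncRNAs, 226 diseases and an expected ~620 associations.

One integer seed drives everything; the ontology and the associations use
independent sub-streams (``default_rng([seed, 0])`` and
``default_rng([seed, 1])``) so either can be regenerated alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationMatrix, DiseaseOntology
from .exceptions import ConfigError

__all__ = ["SyntheticConfig", "generate_ontology", "generate_associations"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape, density and seed of one synthetic problem instance.

    ``density_in``/``density_out`` are Bernoulli association probabilities
    for block-matched and unmatched lncRNA-disease pairs. With the default
    shape (285 x 226, 5 blocks) the expected positive count is
    12882 * 0.0462 + 51528 * 0.0005 ~= 621, i.e. ~96% of associations fall
    inside their block and a small background of cross-block links remains,
    as in real curated catalogs.
    """

    n_lncrnas: int = 285
    n_diseases: int = 226
    n_blocks: int = 5
    density_in: float = 0.0462
    density_out: float = 0.0005
    dag_depth: int = 3
    dag_branching: int = 2
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.density_out < self.density_in <= 1:
            raise ConfigError(
                "densities must satisfy 0 <= density_out < density_in <= 1"
            )
        if self.n_blocks < 1 or self.n_blocks > min(self.n_lncrnas, self.n_diseases):
            raise ConfigError(
                "n_blocks must be between 1 and min(n_lncrnas, n_diseases)"
            )

    @property
    def lncrna_ids(self) -> tuple[str, ...]:
        return tuple(f"L{i:04d}" for i in range(self.n_lncrnas))

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(f"D{j:04d}" for j in range(self.n_diseases))

    def lncrna_blocks(self) -> np.ndarray:
        """Round-robin block label of each lncRNA."""
        return np.arange(self.n_lncrnas) % self.n_blocks

    def disease_blocks(self) -> np.ndarray:
        """Round-robin block label of each disease."""
        return np.arange(self.n_diseases) % self.n_blocks


def generate_ontology(config: SyntheticConfig) -> DiseaseOntology:
    """Build a rooted DAG in which same-block diseases share deep ancestors.

    One global root spans ``n_blocks`` block subgraphs. Each block has a top
    node under the root carrying ``dag_branching`` parallel chains of
    internal nodes of depth ``dag_depth``; every disease term of the block
    is a child of all chain ends, so any two same-block terms share the
    block's entire internal node set as ancestors (their similarity is
    uniformly high), while cross-block terms share only the global root.
    Each disease also gets one extra parent drawn by the seeded generator
    from the shallower internal nodes of its block, giving the irregular
    multi-parent structure of real disease vocabularies.
    """
    if config.dag_depth < 1 or config.dag_branching < 1:
        raise ConfigError("dag_depth and dag_branching must be at least 1")
    rng = np.random.default_rng([config.seed, 0])
    edges: list[tuple[str, str]] = []
    block_deep: list[list[str]] = []
    block_shallow: list[list[str]] = []
    for b in range(config.n_blocks):
        top = f"B{b}"
        edges.append(("ROOT", top))
        deep: list[str] = []
        shallow: list[str] = [top]
        for c in range(config.dag_branching):
            prev = top
            for lvl in range(config.dag_depth - 1):
                node = f"B{b}.{c}.{lvl}"
                edges.append((prev, node))
                shallow.append(node)
                prev = node
            deep.append(prev)
        # dag_depth == 1 collapses every chain onto the block top node
        block_deep.append(sorted(set(deep)))
        block_shallow.append(shallow)

    blocks = config.disease_blocks()
    for j, name in enumerate(config.disease_ids):
        b = blocks[j]
        parents = set(block_deep[b])
        extra = block_shallow[b][rng.integers(len(block_shallow[b]))]
        parents.add(extra)
        for parent in sorted(parents):
            edges.append((parent, name))
    return DiseaseOntology.from_edges(edges)


def generate_associations(
    config: SyntheticConfig,
) -> tuple[AssociationMatrix, dict[str, np.ndarray]]:
    """Draw the planted-block binary association matrix.

    Returns the matrix together with the ground-truth block labels
    (``{"lncrna": ..., "disease": ...}``) for recovery tests. All-zero rows
    and columns may occur, as they do in real curated data.
    """
    rng = np.random.default_rng([config.seed, 1])
    l_blocks = config.lncrna_blocks()
    d_blocks = config.disease_blocks()
    matched = l_blocks[:, None] == d_blocks[None, :]
    prob = np.where(matched, config.density_in, config.density_out)
    values = (rng.random((config.n_lncrnas, config.n_diseases)) < prob).astype(float)
    assoc = AssociationMatrix(values, config.lncrna_ids, config.disease_ids)
    return assoc, {"lncrna": l_blocks, "disease": d_blocks}
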