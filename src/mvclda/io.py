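"""Readers and writers for the package's delimited text formats.

All formats are plain text. The default dialect is tab-separated because
disease names routinely contain commas; every reader takes a ``delimiter``
argument. Readers validate rather than coerce: a malformed row raises a
:class:`~mvclda.exceptions.ParseError` naming the file and line.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AssociationMatrix, DiseaseOntology
from .exceptions import ParseError
from .similarity import SimilarityView

__all__ = [
    "read_association_table",
    "write_association_table",
    "read_ontology",
    "write_ontology",
    "write_predictions",
    "read_predictions",
    "write_similarity_matrix",
]


def _read_rows(path: str | Path, delimiter: str, min_cols: int) -> list[tuple[int, list[str]]]:
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < min_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected at least {min_cols} columns, got {len(row)}"
                )
            rows.append((lineno, [cell.strip() for cell in row]))
    if not rows:
        raise ParseError(f"{path}: file is empty")
    return rows


def read_association_table(path: str | Path, delimiter: str = "\t") -> AssociationMatrix:
    """Read a headered (lncrna_id, disease_id) pair list into a matrix.

    Duplicate pairs are merged; identifier order is first-appearance order;
    identifiers are whitespace-trimmed but case-preserved.
    """
    path = Path(path)
    rows = _read_rows(path, delimiter, min_cols=2)
    pairs: list[tuple[str, str]] = []
    for lineno, row in rows[1:]:  # first row is the header
        l, d = row[0], row[1]
        if not l or not d:
            raise ParseError(f"{path}:{lineno}: empty identifier")
        pairs.append((l, d))
    if not pairs:
        raise ParseError(f"{path}: no association rows after the header")
    return AssociationMatrix.from_pairs(pairs)


def write_association_table(
    assoc: AssociationMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write the known pairs of an association matrix as a headered table."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["lncrna_id", "disease_id"])
        writer.writerows(assoc.pairs())


def read_ontology(path: str | Path, delimiter: str = "\t") -> DiseaseOntology:
    """Read a headered (parent_id, child_id) edge list into a rooted DAG."""
    path = Path(path)
    rows = _read_rows(path, delimiter, min_cols=2)
    edges: list[tuple[str, str]] = []
    for lineno, row in rows[1:]:
        parent, child = row[0], row[1]
        if not parent or not child:
            raise ParseError(f"{path}:{lineno}: empty term identifier")
        if parent == child:
            raise ParseError(f"{path}:{lineno}: self-edge on term {parent!r}")
        edges.append((parent, child))
    return DiseaseOntology.from_edges(edges)


def write_ontology(
    ontology: DiseaseOntology, path: str | Path, delimiter: str = "\t"
) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["parent_id", "child_id"])
        writer.writerows(ontology.edges)


def write_predictions(
    F: np.ndarray,
    lncrna_ids: tuple[str, ...],
    disease_ids: tuple[str, ...],
    known_mask: np.ndarray,
    path: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write all p*q scored pairs as a long table, best score first.

    Columns: lncrna_id, disease_id, score (6 significant digits),
    known_flag (1 if the pair is a known association). Ties are broken by
    (lncrna_id, disease_id) so the ordering is reproducible.
    """
    F = np.asarray(F, dtype=float)
    known_mask = np.asarray(known_mask)
    if F.shape != known_mask.shape or F.shape != (len(lncrna_ids), len(disease_ids)):
        raise ValueError(
            f"inconsistent shapes: F {F.shape}, mask {known_mask.shape}, "
            f"{len(lncrna_ids)} lncRNAs, {len(disease_ids)} diseases"
        )
    table = pd.DataFrame(
        {
            "lncrna_id": np.repeat(lncrna_ids, len(disease_ids)),
            "disease_id": np.tile(disease_ids, len(lncrna_ids)),
            "score": F.ravel(),
            "known_flag": known_mask.astype(int).ravel(),
        }
    )
    table = table.sort_values(
        ["score", "lncrna_id", "disease_id"], ascending=[False, True, True], kind="stable"
    )
    table["score"] = table["score"].map(lambda s: f"{s:.6g}")
    table.to_csv(path, sep=delimiter, index=False)


def read_predictions(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    table = pd.read_csv(path, sep=delimiter)
    expected = ["lncrna_id", "disease_id", "score", "known_flag"]
    if list(table.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(table.columns)}")
    return table


def write_similarity_matrix(
    view: SimilarityView,
    ids: tuple[str, ...],
    path: str | Path,
    delimiter: str = "\t",
) -> None:
    """Export one similarity view as a labeled square matrix."""
    frame = pd.DataFrame(view.values, index=ids, columns=ids)
    frame.to_csv(path, sep=delimiter, index_label="id")
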