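"""Mining a marker table from an annotated reference dataset.

For every unordered pair of cell types, a shallow binary classification
tree is trained on the ordinal-encoded cell signatures (- < m < +) of the
two types; the marker with the largest total impurity decrease is the
pair's discriminant.  If that marker is not yet present in either type's
table entry, both entries receive it, set to the modal level of the
marker within each type.  The greedy guard keeps each entry minimal: a
marker enters the table only by winning a pairwise comparison.

Medium (three-component) modeling must be requested through the reference
labels themselves: a marker is modeled with G = 3 iff some base population
appears under all three suffixed labels ``<base>_<marker>-``,
``<base>_<marker>mid`` and ``<base>_<marker>hi``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .errors import SpecificationError
from .io import AnnotationVector, ExpressionMatrix, UNCLASSIFIED, UNKNOWN
from .signature import SignatureMatrix, build_signature_matrix
from .tables import Group, MarkerTable, MarkerToken

_TREE_MAX_DEPTH = 3
_TREE_MIN_LEAF = 5
_MEDIUM_SUFFIXES = ("-", "mid", "hi")


@dataclass
class PairwiseImportance:
    """Tree-based marker importances for one cell-type pair."""

    pair: tuple[str, str]
    importance: dict[str, float]
    top_marker: str | None  # None when no marker discriminates the pair

    @property
    def is_null(self) -> bool:
        return self.top_marker is None


def detect_medium_markers(labels: AnnotationVector | list[str], marker_names: list[str]) -> dict[str, int]:
    """Markers that reference labels flag for three-level modeling.

    Returns marker -> 3 for each marker M such that some base label appears
    with all three variants ``<base>_<M>-``, ``<base>_<M>mid``,
    ``<base>_<M>hi``; markers without the full triple are left out.
    """
    label_list = labels.labels if isinstance(labels, AnnotationVector) else list(labels)
    unique = set(label_list)
    out: dict[str, int] = {}
    for marker in marker_names:
        bases: dict[str, set[str]] = {}
        for label in unique:
            for suffix in _MEDIUM_SUFFIXES:
                tail = f"_{marker}{suffix}"
                if label.endswith(tail):
                    bases.setdefault(label[: -len(tail)], set()).add(suffix)
        if any(found == set(_MEDIUM_SUFFIXES) for found in bases.values()):
            out[marker] = 3
    return out


def pairwise_top_marker(
    encoded: np.ndarray, marker_names: list[str], is_second: np.ndarray, pair: tuple[str, str]
) -> PairwiseImportance:
    """Most discriminant marker between two cell types.

    ``encoded`` holds the ordinal signatures (0/1/2) of the pair's cells
    and ``is_second`` the binary class labels.  Importance is sklearn's
    impurity-decrease attribution over the tree's (primary) splits; ties
    resolve to the first marker in matrix order.  When no split separates
    the classes a null record is returned.
    """
    if is_second.all() or (~is_second).all():
        raise SpecificationError("both classes must be non-empty")
    tree = DecisionTreeClassifier(
        criterion="gini",
        max_depth=_TREE_MAX_DEPTH,
        min_samples_leaf=min(_TREE_MIN_LEAF, max(1, len(is_second) // 4)),
        random_state=0,
    )
    tree.fit(encoded, is_second.astype(int))
    importances = np.asarray(tree.feature_importances_, dtype=float)
    # identical columns are perfect surrogates of each other: give them the
    # split feature's credit, so redundant markers tie deterministically
    _, group = np.unique(encoded, axis=1, return_inverse=True)
    for gid in np.unique(group):
        members = group == gid
        importances[members] = importances[members].max()
    if tree.tree_.node_count <= 1 or not np.any(importances > 0):
        return PairwiseImportance(pair=pair, importance=dict(zip(marker_names, importances)), top_marker=None)
    top = int(np.argmax(importances))  # argmax takes the first maximum
    return PairwiseImportance(
        pair=pair,
        importance=dict(zip(marker_names, importances.astype(float))),
        top_marker=marker_names[top],
    )


def set_marker_expression(column: np.ndarray) -> str:
    """Modal level symbol of a marker over a cell subset; ties break toward
    the higher-priority symbol (+ > m > -)."""
    if column.size == 0:
        raise SpecificationError("cell subset must be non-empty")
    best_symbol, best_count = "-", -1
    for symbol in ("+", "m", "-"):  # priority order: first winner kept on ties
        count = int((column == symbol).sum())
        if count > best_count:
            best_symbol, best_count = symbol, count
    return best_symbol


def extract_marker_table(
    matrix: ExpressionMatrix,
    labels: AnnotationVector | list[str],
    variance_mode: str = "E",
    use_rss: bool = False,
    seed: int = 0,
    min_cells_per_type: int = 20,
    exclude_unknown: bool = True,
) -> MarkerTable:
    """Mine a marker table from an annotated dataset.

    Cell signatures are computed for all markers (G per marker from
    :func:`detect_medium_markers`, default 2); cell-type pairs are visited
    in lexicographic order and each pair contributes its top discriminant
    marker to both entries unless either entry already mentions it.
    Cells labeled unknown/unclassified are excluded by default.
    Returns the accumulated table; unmentioned markers are wildcards.
    """
    label_arr = np.asarray(
        labels.labels if isinstance(labels, AnnotationVector) else labels, dtype=object
    )
    if len(label_arr) != matrix.n_cells:
        raise SpecificationError("labels length does not match cell count")
    keep = np.ones(len(label_arr), dtype=bool)
    if exclude_unknown:
        keep = ~np.isin(label_arr, (UNKNOWN, UNCLASSIFIED))
    types = sorted(set(label_arr[keep]))
    if len(types) < 2:
        raise SpecificationError("training needs at least two cell types")
    small = [t for t in types if (label_arr == t).sum() < min_cells_per_type]
    if small:
        warnings.warn(f"cell types below the {min_cells_per_type}-cell floor: {small}")

    levels = {m: 2 for m in matrix.marker_names}
    levels.update(detect_medium_markers(label_arr.tolist(), matrix.marker_names))
    signatures, _ = build_signature_matrix(
        matrix, levels, variance_mode=variance_mode, use_rss=use_rss, seed=seed
    )
    encoded = signatures.encoded()

    entries: dict[str, dict[str, str]] = {t: {} for t in types}
    indistinguishable: list[tuple[str, str]] = []
    for t1, t2 in itertools.combinations(types, 2):
        mask1 = label_arr == t1
        mask2 = label_arr == t2
        rows = np.flatnonzero(mask1 | mask2)
        record = pairwise_top_marker(
            encoded[rows], signatures.marker_names, mask2[rows], (t1, t2)
        )
        if record.is_null:
            indistinguishable.append((t1, t2))
            continue
        marker = record.top_marker
        # greedy guard: the pair's winner enters only the entries that do not
        # already constrain it; an existing symbol is never overwritten
        col = signatures.column(marker)
        if marker not in entries[t1]:
            entries[t1][marker] = set_marker_expression(col[mask1])
        if marker not in entries[t2]:
            entries[t2][marker] = set_marker_expression(col[mask2])

    if indistinguishable:
        warnings.warn(
            "cell-type pairs with no discriminating marker: "
            + ", ".join(f"{a}/{b}" for a, b in indistinguishable)
        )

    table_entries: dict[str, list[Group]] = {}
    for cell_type in types:
        table_entries[cell_type] = [
            (MarkerToken(marker, level, "AND"),)
            for marker, level in entries[cell_type].items()
        ]
    return MarkerTable(entries=table_entries, marker_universe=list(matrix.marker_names))
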