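"""Annotating a dataset from a marker table.

The pipeline: (1) optionally draw a simple random sample of cells; (2)
compile the table into a priority-ordered signature dictionary; (3) call
each sampled cell's per-marker expression levels and match its signature
against the dictionary, leaving non-matching cells unclassified; (4)
refine.  Without the reject option, refinement is a plain k-NN vote: the
matched cells train, everyone else (unmatched plus unsampled) queries.
With the reject option, mutual nearest neighbors (MNN) between the matched
set A and the unmatched set U first carve out a confident core: matched
cells with too many cross-set MNNs are deemed ambiguous and re-queried,
while unmatched cells with no MNN into A are confident unknowns — they
keep the reserved label "unknown" and join the k-NN training set, letting
genuinely novel populations survive refinement instead of being absorbed
into the nearest table-defined type.

All distances are Euclidean over the table's markers in the (transformed)
intensity space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import ParameterError, SpecificationError
from .io import AnnotationVector, ExpressionMatrix, UNCLASSIFIED, UNKNOWN
from .signature import build_signature_matrix, SignatureMatrix
from .tables import MarkerTable, SignatureDictionary, build_dictionary, required_levels

_SRS_FLOOR = 500


@dataclass
class AnnotationParams:
    """Tunable knobs of the annotation pipeline (defaults as documented)."""

    variance_mode: str = "E"
    use_rss: bool | None = None  # None: coupled to variance mode (on for V)
    srs_fraction: float = 0.1
    reject_option: bool = False
    k: int = 10
    seed: int = 42
    ambiguity_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.variance_mode not in ("E", "V"):
            raise ParameterError(f"variance_mode must be 'E' or 'V', got {self.variance_mode!r}")
        if not (0 < self.srs_fraction <= 1):
            raise ParameterError("srs_fraction must lie in (0, 1]")
        if self.k < 1:
            raise ParameterError("k must be >= 1")

    @property
    def rss_enabled(self) -> bool:
        return self.use_rss if self.use_rss is not None else (self.variance_mode == "V")


@dataclass
class AnnotationState:
    """Index bookkeeping across the pipeline stages."""

    sampled: np.ndarray
    annotated: np.ndarray  # A: matched sampled cells
    unclassified: np.ndarray  # U: unmatched sampled cells
    annotated_confident: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    unknown_confident: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def simple_random_sample(n_cells: int, fraction: float, seed: int) -> np.ndarray:
    """Uniform sample without replacement of max(ceil(f*n), min(n, 500))
    indices; fraction 1 returns all indices."""
    if not (0 < fraction <= 1):
        raise ParameterError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return np.arange(n_cells)
    size = min(n_cells, max(int(np.ceil(fraction * n_cells)), min(n_cells, _SRS_FLOOR)))
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_cells, size=size, replace=False))


def match_signatures(signatures: SignatureMatrix, dictionary: SignatureDictionary) -> list[str]:
    """Best-priority dictionary cell type per cell, or "unclassified".

    Evaluated vectorized: entries are visited in priority order and each
    claims the still-unlabeled cells its predicate admits.
    """
    missing = [m for m in dictionary.marker_universe if m not in signatures.marker_names]
    if missing:
        raise SpecificationError(f"signature matrix lacks dictionary markers: {missing}")
    n = signatures.n_cells
    cols = {m: signatures.column(m) for m in dictionary.marker_universe}
    labels = np.full(n, UNCLASSIFIED, dtype=object)
    unlabeled = np.ones(n, dtype=bool)
    for cell_type, _, _ in dictionary._ordered:
        if not unlabeled.any():
            break
        holds = np.ones(n, dtype=bool)
        for group in dictionary.table.entries[cell_type]:
            op = group[0].operator
            token_hits = [
                np.ones(n, dtype=bool) if t.level == "*" else (cols[t.marker] == t.level)
                for t in group
            ]
            if op == "AND":
                for hit in token_hits:
                    holds &= hit
            elif op == "OR":
                holds &= np.logical_or.reduce(token_hits)
            else:  # XOR: exactly one token holds
                holds &= np.sum(token_hits, axis=0) == 1
        claim = holds & unlabeled
        labels[claim] = cell_type
        unlabeled &= ~claim
    return labels.tolist()


def mutual_nearest_neighbors(
    X_a: np.ndarray, X_u: np.ndarray, k: int
) -> set[tuple[int, int]]:
    """Cross-set MNN pairs (i, j): j is among the k nearest of a_i within
    X_u and a_i among the k nearest of u_j within X_a (Euclidean)."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if len(X_a) == 0 or len(X_u) == 0:
        return set()
    k_au = min(k, len(X_u))
    k_ua = min(k, len(X_a))
    nn_u = NearestNeighbors(n_neighbors=k_au).fit(X_u)
    a_to_u = nn_u.kneighbors(X_a, return_distance=False)
    nn_a = NearestNeighbors(n_neighbors=k_ua).fit(X_a)
    u_to_a = nn_a.kneighbors(X_u, return_distance=False)
    u_sets = [set(row) for row in u_to_a]
    pairs = set()
    for i, row in enumerate(a_to_u):
        for j in row:
            if i in u_sets[j]:
                pairs.add((i, int(j)))
    return pairs


def build_confident_sets(
    n_annotated: int, n_unclassified: int, mnn_pairs: set[tuple[int, int]], k: int,
    ambiguity_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Split A and U on MNN evidence.

    An annotated cell whose MNN-pair count exceeds ``ambiguity_threshold *
    k`` is ambiguous (likely a matching error) and drops out of the
    confident annotated set; an unclassified cell with zero MNN pairs into
    A is a confident unknown.  Returns boolean masks (confident_annotated,
    confident_unknown).
    """
    pair_counts_a = np.zeros(n_annotated, dtype=int)
    has_pair_u = np.zeros(n_unclassified, dtype=bool)
    for i, j in mnn_pairs:
        pair_counts_a[i] += 1
        has_pair_u[j] = True
    confident_a = pair_counts_a / k <= ambiguity_threshold
    confident_u = ~has_pair_u
    return confident_a, confident_u


def knn_refine(
    X_train: np.ndarray, train_labels: list[str], X_query: np.ndarray, k: int
) -> list[str]:
    """Majority vote among the k nearest training cells; vote ties break to
    the label of the single nearest neighbor."""
    if len(X_train) == 0:
        raise ParameterError("k-NN refinement needs a non-empty training set")
    if len(X_query) == 0:
        return []
    if k > len(X_train):
        warnings.warn(f"k={k} exceeds training size {len(X_train)}; clamped")
        k = len(X_train)
    nn = NearestNeighbors(n_neighbors=k).fit(X_train)
    neigh = nn.kneighbors(X_query, return_distance=False)
    labels_arr = np.asarray(train_labels, dtype=object)
    out: list[str] = []
    for row in neigh:
        votes: dict[str, int] = {}
        for idx in row:
            lab = labels_arr[idx]
            votes[lab] = votes.get(lab, 0) + 1
        best = max(votes.values())
        winners = [lab for lab, c in votes.items() if c == best]
        if len(winners) == 1:
            out.append(winners[0])
        else:  # tie: the nearest neighbor (rows are distance-sorted) decides
            nearest_label = next(
                labels_arr[idx] for idx in row if labels_arr[idx] in winners
            )
            out.append(nearest_label)
    return out


def annotate(
    matrix: ExpressionMatrix,
    table: MarkerTable,
    params: AnnotationParams | None = None,
) -> AnnotationVector:
    """Run the full annotation pipeline; see the module docstring."""
    params = params or AnnotationParams()
    missing = [m for m in table.marker_universe if m not in matrix.marker_names]
    if missing:
        raise SpecificationError(
            f"marker table references markers absent from the matrix: {missing}"
        )
    n = matrix.n_cells
    dictionary = build_dictionary(table)
    markers = dictionary.marker_universe

    sampled = simple_random_sample(n, params.srs_fraction, params.seed)
    sampled_matrix = ExpressionMatrix(
        values=matrix.values[sampled],
        marker_names=list(matrix.marker_names),
        cell_ids=[matrix.cell_ids[i] for i in sampled],
    )
    signatures, _ = build_signature_matrix(
        sampled_matrix,
        required_levels(table),
        variance_mode=params.variance_mode,
        use_rss=params.rss_enabled,
        seed=params.seed,
    )
    matched = match_signatures(signatures, dictionary)

    labels = np.full(n, UNCLASSIFIED, dtype=object)
    provenance = np.full(n, "unsampled->refined", dtype=object)
    labels[sampled] = matched
    provenance[sampled] = "refined"

    matched_arr = np.asarray(matched, dtype=object)
    A = sampled[matched_arr != UNCLASSIFIED]
    U = sampled[matched_arr == UNCLASSIFIED]
    provenance[A] = "direct"
    unsampled = np.setdiff1d(np.arange(n), sampled, assume_unique=False)

    X = matrix.subset_markers(markers)

    if not params.reject_option:
        queries = np.concatenate([U, unsampled])
        if len(A) == 0:
            warnings.warn("no cell matched the table; all cells left unclassified")
            return AnnotationVector(labels=labels.tolist(), provenance=provenance.tolist())
        if len(queries):
            labels[queries] = knn_refine(X[A], labels[A].tolist(), X[queries], params.k)
        return AnnotationVector(labels=labels.tolist(), provenance=provenance.tolist())

    # reject option: MNN between matched (A) and unmatched-but-sampled (U)
    pairs = mutual_nearest_neighbors(X[A], X[U], params.k)
    conf_a_mask, conf_u_mask = build_confident_sets(
        len(A), len(U), pairs, params.k, params.ambiguity_threshold
    )
    A_conf = A[conf_a_mask]
    ambiguous = A[~conf_a_mask]
    U_conf = U[conf_u_mask]

    labels[U_conf] = UNKNOWN
    provenance[U_conf] = "unknown"
    train_idx = np.concatenate([A_conf, U_conf])
    queries = np.concatenate([U[~conf_u_mask], ambiguous, unsampled])
    if len(train_idx) == 0:
        warnings.warn("confident sets are empty; all cells left unclassified")
        return AnnotationVector(labels=labels.tolist(), provenance=provenance.tolist())
    if len(queries):
        refined = knn_refine(X[train_idx], labels[train_idx].tolist(), X[queries], params.k)
        labels[queries] = refined
        provenance[ambiguous] = "refined"
    return AnnotationVector(labels=labels.tolist(), provenance=provenance.tolist())
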