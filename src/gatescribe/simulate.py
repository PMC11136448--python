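"""Seeded synthetic cytometry datasets with known ground truth.

The generator works backwards from a ground-truth marker table: each cell
draws a cell type from the stated proportions, then a concrete signature
uniformly from that type's expansion (so wildcard and operator branches
are all exercised), and finally each marker's intensity from the Gaussian
component of the signature's level.  With adjacent level means separated
by several standard deviations, the generating labels are recoverable by
midpoint thresholding, which gives the rest of the package an exact
oracle.  An optional extra population, absent from the table and well
separated on at least one marker, emulates a novel cell subset for
reject-option testing.

What this emulates: per-marker mixtures of 2-3 Gaussian components on a
transformed intensity scale.  What it does not: spillover, doublets,
debris, acquisition drift, or the heavy skew of raw (untransformed) data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import SpecificationError
from .io import AnnotationVector, ExpressionMatrix, UNKNOWN
from .tables import MarkerTable, expand_cell_type, required_levels, table_from_strings


@dataclass
class UnknownSpec:
    """A planted population outside the table's vocabulary."""

    n_cells: int
    marker_means: dict[str, float]  # mean per marker; sd shared below
    sd: float = 0.3


@dataclass
class GeneratorSpec:
    """Everything needed to draw one synthetic dataset."""

    table: MarkerTable
    proportions: dict[str, float]
    component_params: dict[str, dict[str, tuple[float, float]]]  # marker -> level -> (mean, sd)
    n_cells: int = 10_000
    seed: int = 0
    unknown_spec: UnknownSpec | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise SpecificationError("cell-type proportions must sum to 1")
        if set(self.proportions) != set(self.table.entries):
            raise SpecificationError("proportions must cover exactly the table's cell types")
        for marker, levels in self.component_params.items():
            means = [levels[lv][0] for lv in ("-", "m", "+") if lv in levels]
            if any(b <= a for a, b in zip(means, means[1:])):
                raise SpecificationError(
                    f"level means for {marker} must increase - < m < +"
                )
            if any(sd <= 0 for _, sd in levels.values()):
                raise SpecificationError(f"non-positive sd for marker {marker}")


def generate_dataset(spec: GeneratorSpec) -> tuple[ExpressionMatrix, AnnotationVector]:
    """Draw a labeled expression matrix from the ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    markers = spec.table.marker_universe
    levels = required_levels(spec.table)
    types = list(spec.proportions)
    probs = np.array([spec.proportions[t] for t in types])

    expansions: dict[str, list[tuple[str, ...]]] = {}
    for cell_type in types:
        sigs = sorted(
            expand_cell_type(spec.table.entries[cell_type], markers, levels)
        )
        if not sigs:
            raise SpecificationError(f"entry {cell_type!r} admits no signature")
        expansions[cell_type] = sigs

    type_idx = rng.choice(len(types), size=spec.n_cells, p=probs)
    values = np.empty((spec.n_cells, len(markers)))
    labels = [types[i] for i in type_idx]
    # per cell: a uniformly chosen concrete signature of its type
    sig_codes = np.empty((spec.n_cells, len(markers)), dtype="<U1")
    for t, cell_type in enumerate(types):
        rows = np.flatnonzero(type_idx == t)
        sigs = expansions[cell_type]
        picks = rng.integers(len(sigs), size=len(rows))
        arr = np.array(sigs)  # (n_sigs, n_markers) of symbols
        sig_codes[rows] = arr[picks]
    for j, marker in enumerate(markers):
        for level in ("-", "m", "+"):
            mask = sig_codes[:, j] == level
            if not mask.any():
                continue
            if level not in spec.component_params[marker]:
                raise SpecificationError(
                    f"no component parameters for {marker} level {level!r}"
                )
            mean, sd = spec.component_params[marker][level]
            values[mask, j] = rng.normal(mean, sd, size=int(mask.sum()))

    matrix = ExpressionMatrix(values=values, marker_names=list(markers))
    annotation = AnnotationVector(labels=labels)
    if spec.unknown_spec is not None and spec.unknown_spec.n_cells > 0:
        matrix, annotation = plant_unknown_population(matrix, annotation, spec)
    return matrix, annotation


def plant_unknown_population(
    matrix: ExpressionMatrix, labels: AnnotationVector, spec: GeneratorSpec
) -> tuple[ExpressionMatrix, AnnotationVector]:
    """Append cells from a population the table does not describe.

    The planted component must sit at >= 8 sd from every table-defined
    level mean on at least one marker, so that "unknown" is geometrically
    identifiable; the margin is verified before any cell is drawn.
    """
    unk = spec.unknown_spec
    if unk is None or unk.n_cells == 0:
        return matrix, labels
    margins = {}
    for marker, mean in unk.marker_means.items():
        if marker not in matrix.marker_names:
            raise SpecificationError(f"unknown-population marker {marker!r} not in matrix")
        level_params = spec.component_params.get(marker, {})
        if not level_params:
            continue
        gaps = [
            abs(mean - m) / max(sd, unk.sd) for m, sd in level_params.values()
        ]
        margins[marker] = min(gaps)
    best = max(margins.values(), default=0.0)
    if best < 8.0:
        raise SpecificationError(
            f"planted population separation {best:.1f} sd < 8 sd on every marker"
        )
    rng = np.random.default_rng((spec.seed + 1) % (2**31))
    block = np.empty((unk.n_cells, matrix.n_markers))
    for j, marker in enumerate(matrix.marker_names):
        mean = unk.marker_means.get(marker)
        if mean is None:  # markers the unknown spec leaves free: negative level
            mean = spec.component_params[marker]["-"][0]
        block[:, j] = rng.normal(mean, unk.sd, size=unk.n_cells)
    values = np.vstack([matrix.values, block])
    out_matrix = ExpressionMatrix(values=values, marker_names=list(matrix.marker_names))
    out_labels = AnnotationVector(
        labels=labels.labels + [UNKNOWN] * unk.n_cells,
        provenance=labels.provenance + ["direct"] * unk.n_cells,
    )
    return out_matrix, out_labels


# ---------------------------------------------------------------------------
# The standard benchmark construction used throughout the test suite
# ---------------------------------------------------------------------------

def standard_table() -> MarkerTable:
    """A 4-type, 6-marker gating design: two discriminating markers per
    adjacent pair plus two uninformative wildcard markers."""
    return table_from_strings(
        {
            "Tcell": "CD3+,CD19-",
            "Bcell": "CD3-,CD19+",
            "Mono": "CD3-,CD19-,CD14+",
            "NK": "CD3-,CD19-,CD14-,CD56+",
        },
        marker_universe=["CD3", "CD19", "CD14", "CD56", "CD45", "HLA-DR"],
    )


def standard_components(
    separation_sd: float = 6.0, sd: float = 0.3, markers: Mapping[str, int] | None = None
) -> dict[str, dict[str, tuple[float, float]]]:
    """Level components with adjacent means ``separation_sd`` sds apart."""
    table = standard_table()
    gap = separation_sd * sd
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for marker in table.marker_universe:
        out[marker] = {"-": (0.0, sd), "+": (gap, sd)}
    return out


def standard_spec(
    n_cells: int = 10_000,
    seed: int = 0,
    separation_sd: float = 6.0,
    unknown_fraction: float = 0.0,
) -> GeneratorSpec:
    """The default study conditions: 4 types at 40/30/20/10%, 6 sd level
    separation, optional planted unknown population at +10 sd on CD45."""
    table = standard_table()
    components = standard_components(separation_sd=separation_sd)
    unknown = None
    if unknown_fraction > 0:
        unknown = UnknownSpec(
            n_cells=int(round(unknown_fraction * n_cells)),
            marker_means={"CD45": 10 * 0.3 + components["CD45"]["+"][0]},
            sd=0.3,
        )
    return GeneratorSpec(
        table=table,
        proportions={"Tcell": 0.4, "Bcell": 0.3, "Mono": 0.2, "NK": 0.1},
        component_params=components,
        n_cells=n_cells,
        seed=seed,
        unknown_spec=unknown,
    )


def oracle_labels(matrix: ExpressionMatrix, spec: GeneratorSpec) -> list[str]:
    """Midpoint-threshold classifier for well-separated designs (test oracle).

    Calls each marker's level by nearest level mean and looks the signature
    up in the ground-truth table; independent of any mixture fitting.
    """
    from .tables import build_dictionary

    markers = spec.table.marker_universe
    levels = required_levels(spec.table)
    symbols = np.empty((matrix.n_cells, len(markers)), dtype="<U1")
    for j, marker in enumerate(markers):
        lvls = [lv for lv in ("-", "m", "+") if lv in spec.component_params[marker]]
        means = np.array([spec.component_params[marker][lv][0] for lv in lvls])
        nearest = np.argmin(
            np.abs(matrix.values[:, matrix.marker_names.index(marker)][:, None] - means[None, :]),
            axis=1,
        )
        symbols[:, j] = np.array(lvls)[nearest]
    dictionary = build_dictionary(spec.table, levels)
    out = []
    for i in range(matrix.n_cells):
        label = dictionary.lookup(dict(zip(markers, symbols[i])))
        out.append(label if label is not None else "unclassified")
    return out
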