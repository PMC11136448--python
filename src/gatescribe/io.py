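"""Readers and writers for cytometry expression matrices, marker tables
and annotation outputs.

Expression matrices arrive as CSV/TSV (header of marker names, optional
leading cell-id column) or as FCS 3.0/3.1 list-mode files.  The FCS support
here is deliberately minimal: float ($DATATYPE F) and double (D) list-mode
data, little- or big-endian, which covers post-acquisition exports; integer
bit-masked data and analysis segments are out of scope.  Values are
returned untransformed — cytometry intensities are expected to be
compensated and variance-stabilized upstream, with :func:`arcsinh_transform`
offered as an explicit opt-in.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CorruptFileError,
    FormatError,
    ParameterError,
    ParseError,
    UnsupportedFormatError,
)
from .tables import (
    Group,
    MarkerTable,
    MarkerToken,
    parse_signature_string,
    serialize_groups,
)

UNCLASSIFIED = "unclassified"
UNKNOWN = "unknown"

PROVENANCE_TAGS = ("direct", "refined", "unknown", "unsampled->refined")


@dataclass
class ExpressionMatrix:
    """Cells x markers matrix of continuous (transformed) intensities."""

    values: np.ndarray
    marker_names: list[str]
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        if self.values.shape[0] < 1:
            raise FormatError("expression matrix needs at least one cell")
        if len(self.marker_names) != self.values.shape[1]:
            raise FormatError("marker_names length does not match column count")
        if len(set(self.marker_names)) != len(self.marker_names):
            dupes = sorted({m for m in self.marker_names if self.marker_names.count(m) > 1})
            raise FormatError(f"duplicate marker names: {dupes}")
        if not self.marker_names:
            raise FormatError("at least one marker is required")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression matrix contains non-finite values")
        if not self.cell_ids:
            self.cell_ids = [str(i) for i in range(self.values.shape[0])]
        if len(self.cell_ids) != self.values.shape[0]:
            raise FormatError("cell_ids length does not match row count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def column(self, marker: str) -> np.ndarray:
        return self.values[:, self.marker_names.index(marker)]

    def subset_markers(self, markers: Sequence[str]) -> np.ndarray:
        idx = [self.marker_names.index(m) for m in markers]
        return self.values[:, idx]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.marker_names, index=self.cell_ids)


@dataclass
class AnnotationVector:
    """Per-cell labels plus a provenance tag for how each was assigned."""

    labels: list[str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = ["direct"] * len(self.labels)
        if len(self.provenance) != len(self.labels):
            raise FormatError("provenance length does not match labels")

    def __len__(self) -> int:
        return len(self.labels)


def read_expression_csv(path: str | Path, delimiter: str = ",") -> ExpressionMatrix:
    """Read a cells x markers CSV/TSV; the first column is used as cell ids
    when its header is empty or a recognized id name."""
    with open(path, newline="") as fh:
        raw_header = next(csv.reader(fh, delimiter=delimiter), [])
    body = [h.strip() for h in raw_header[1:]] if raw_header else []
    if raw_header and len(set(body)) != len(body) or len(set(raw_header)) != len(raw_header):
        raise FormatError(f"{path}: duplicate marker names in header")
    df = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    first = str(df.columns[0])
    cell_ids: list[str] = []
    if first.lower() in ("", "cell_id", "cellid", "id", "unnamed: 0"):
        cell_ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    markers = [str(c) for c in df.columns]
    if len(set(markers)) != len(markers):
        raise FormatError(f"{path}: duplicate marker names in header")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ParseError(
                    f"{path}: non-numeric value {df[col][bad[0]]!r} at row "
                    f"{bad[0] + 2}, column {col!r}"
                ) from None
        raise
    return ExpressionMatrix(values=values, marker_names=markers, cell_ids=cell_ids)


def write_expression_csv(matrix: ExpressionMatrix, path: str | Path, delimiter: str = ",") -> None:
    matrix.to_dataframe().to_csv(path, sep=delimiter, index_label="cell_id")


def arcsinh_transform(matrix: ExpressionMatrix, cofactor: float = 5.0) -> ExpressionMatrix:
    """Apply the cytometry-standard asinh(x / cofactor) variance-stabilizer."""
    if cofactor <= 0:
        raise ParameterError(f"cofactor must be positive, got {cofactor}")
    return ExpressionMatrix(
        values=np.arcsinh(matrix.values / cofactor),
        marker_names=list(matrix.marker_names),
        cell_ids=list(matrix.cell_ids),
    )


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 (minimal list-mode float support)
# ---------------------------------------------------------------------------

_FCS_VERSIONS = (b"FCS3.0", b"FCS3.1")


def _read_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise CorruptFileError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1").strip(delim)
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        parts = parts[:-1]
    return {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}


def read_fcs(path: str | Path) -> ExpressionMatrix:
    """Read an FCS 3.0/3.1 list-mode file with float or double data.

    Marker names come from $PnS when present, else $PnN.  No transform is
    applied.  Integer ($DATATYPE I) and ASCII data, and non-list modes,
    raise :class:`UnsupportedFormatError`.
    """
    data = Path(path).read_bytes()
    if len(data) < 58:
        raise CorruptFileError(f"{path}: shorter than an FCS header")
    if data[:6] not in _FCS_VERSIONS:
        raise UnsupportedFormatError(f"{path}: not an FCS 3.0/3.1 file")

    def _offset(segment: bytes) -> int:
        try:
            return int(segment.decode("ascii").strip() or "0")
        except ValueError as exc:
            raise CorruptFileError(f"{path}: malformed header offset") from exc

    text_begin, text_end = _offset(data[10:18]), _offset(data[18:26])
    data_begin, data_end = _offset(data[26:34]), _offset(data[34:42])
    if text_end <= text_begin or text_end >= len(data):
        raise CorruptFileError(f"{path}: TEXT segment offsets inconsistent with file size")
    keywords = _read_text_segment(data[text_begin : text_end + 1])

    if data_begin == 0:
        data_begin = int(keywords.get("$BEGINDATA", 0))
        data_end = int(keywords.get("$ENDDATA", 0))
    for key in ("$TOT", "$PAR", "$DATATYPE", "$BYTEORD"):
        if key not in keywords:
            raise CorruptFileError(f"{path}: missing required keyword {key}")
    mode = keywords.get("$MODE", "L").upper()
    if mode != "L":
        raise UnsupportedFormatError(f"{path}: $MODE={mode} unsupported (list mode only)")
    datatype = keywords["$DATATYPE"].upper()
    if datatype not in ("F", "D"):
        raise UnsupportedFormatError(
            f"{path}: $DATATYPE={datatype} unsupported (only F and D)"
        )
    n_cells = int(keywords["$TOT"])
    n_par = int(keywords["$PAR"])
    byteord = keywords["$BYTEORD"].replace(" ", "")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise UnsupportedFormatError(f"{path}: $BYTEORD={byteord} unsupported")

    itemsize = 4 if datatype == "F" else 8
    expected = n_cells * n_par * itemsize
    if data_end < data_begin or data_begin + expected - 1 > len(data) - 1 or data_begin <= 0:
        raise CorruptFileError(
            f"{path}: DATA segment ({data_begin}-{data_end}) inconsistent with "
            f"{n_cells}x{n_par} {datatype} events in a {len(data)}-byte file"
        )
    dtype = np.dtype(f"{endian}f{itemsize}")
    values = np.frombuffer(data[data_begin : data_begin + expected], dtype=dtype)
    values = values.reshape(n_cells, n_par).astype(float)

    names = []
    for i in range(1, n_par + 1):
        name = keywords.get(f"$P{i}S") or keywords.get(f"$P{i}N") or f"P{i}"
        names.append(name)
    return ExpressionMatrix(values=values, marker_names=names)


def write_fcs(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a minimal FCS 3.1 list-mode file (float32, little-endian).

    Intended for fixtures and round-trip testing; no analysis segment and
    no keyword preservation.
    """
    n_cells, n_par = matrix.values.shape
    payload = matrix.values.astype("<f4").tobytes()
    delim = "/"
    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$TOT", str(n_cells)),
        ("$PAR", str(n_par)),
    ]
    for i, name in enumerate(matrix.marker_names, start=1):
        keywords.append((f"$P{i}N", name))
        keywords.append((f"$P{i}B", "32"))
        keywords.append((f"$P{i}E", "0,0"))
        keywords.append((f"$P{i}R", str(int(np.ceil(np.abs(matrix.values).max() + 1)))))

    # TEXT length depends on the DATA offsets it contains; iterate to fixed point
    text_begin = 58
    data_begin = 0
    for _ in range(4):
        text = delim + delim.join(
            f"{k}{delim}{v}"
            for k, v in keywords
            + [("$BEGINDATA", str(data_begin)), ("$ENDDATA", str(data_begin + len(payload) - 1))]
        ) + delim
        new_data_begin = text_begin + len(text)
        if new_data_begin == data_begin:
            break
        data_begin = new_data_begin
    text_end = text_begin + len(text) - 1
    data_end = data_begin + len(payload) - 1
    header = (
        b"FCS3.1    "
        + f"{text_begin:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{data_begin:>8d}".encode()
        + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == 58
    Path(path).write_bytes(header + text.encode("latin-1") + payload)


# ---------------------------------------------------------------------------
# Marker-table CSV dialects
# ---------------------------------------------------------------------------

_WIDE_SYMBOLS = {"+", "-", "m", "*", "", "−", "hi", "mid", "lo"}


def read_marker_table(path: str | Path, dialect: str = "wide") -> MarkerTable:
    """Read a marker table CSV.

    wide dialect: one row per cell type, one column per marker, cells in
    {+, -, m, *, blank}; blank means wildcard.  compact dialect: columns
    ``cell_type, signature`` where the signature string follows the gating
    grammar of :mod:`gatescribe.tables`.
    """
    if dialect == "wide":
        return _read_wide(path)
    if dialect == "compact":
        return _read_compact(path)
    raise ParameterError(f"unknown marker-table dialect {dialect!r}")


def _read_wide(path: str | Path) -> MarkerTable:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows[0]) < 2:
        raise FormatError(f"{path}: wide marker table needs a header with markers")
    markers = [c.strip() for c in rows[0][1:]]
    if len(set(markers)) != len(markers):
        raise FormatError(f"{path}: duplicate marker columns")
    entries: dict[str, list[Group]] = {}
    for r, row in enumerate(rows[1:], start=2):
        if not row or not row[0].strip():
            continue
        cell_type = row[0].strip()
        if cell_type in entries:
            raise FormatError(f"{path}: duplicate cell type {cell_type!r} at row {r}")
        groups: list[Group] = []
        cells = row[1:] + [""] * (len(markers) - len(row) + 1)
        for marker, cell in zip(markers, cells):
            symbol = cell.strip()
            if symbol not in _WIDE_SYMBOLS:
                raise FormatError(
                    f"{path}: unknown symbol {symbol!r} at row {r}, column {marker!r}"
                )
            if symbol in ("", "*"):
                continue  # blank or explicit wildcard: marker unconstrained
            level = {"−": "-", "hi": "+", "mid": "m", "lo": "-"}.get(symbol, symbol)
            groups.append((MarkerToken(marker, level, "AND"),))
        entries[cell_type] = groups
    return MarkerTable(entries=entries, marker_universe=markers)


def _read_compact(path: str | Path) -> MarkerTable:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames[:2]] != [
            "cell_type",
            "signature",
        ]:
            raise FormatError(f"{path}: compact dialect needs columns cell_type,signature")
        entries: dict[str, list[Group]] = {}
        for r, row in enumerate(reader, start=2):
            cell_type = (row["cell_type"] or "").strip()
            if not cell_type:
                continue
            if cell_type in entries:
                raise FormatError(f"{path}: duplicate cell type {cell_type!r} at row {r}")
            entries[cell_type] = parse_signature_string(row["signature"] or "")
    return MarkerTable(entries=entries)


def write_marker_table(table: MarkerTable, path: str | Path, dialect: str = "wide") -> None:
    if dialect == "compact":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["cell_type", "signature"])
            for cell_type, groups in table.entries.items():
                writer.writerow([cell_type, serialize_groups(groups)])
        return
    if dialect != "wide":
        raise ParameterError(f"unknown marker-table dialect {dialect!r}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_type"] + table.marker_universe)
        for cell_type, groups in table.entries.items():
            symbols = {m: "*" for m in table.marker_universe}
            for group in groups:
                if group[0].operator != "AND":
                    raise FormatError(
                        f"entry {cell_type!r} uses operators; the wide dialect "
                        "cannot express OR/XOR groups — use dialect='compact'"
                    )
                symbols[group[0].marker] = group[0].level
            writer.writerow([cell_type] + [symbols[m] for m in table.marker_universe])


# ---------------------------------------------------------------------------
# Annotation output
# ---------------------------------------------------------------------------

def write_annotation_csv(
    annotation: AnnotationVector, cell_ids: Iterable[str], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "label", "provenance"])
        for cid, label, prov in zip(cell_ids, annotation.labels, annotation.provenance):
            writer.writerow([cid, label, prov])


def read_annotation_csv(path: str | Path) -> tuple[list[str], AnnotationVector]:
    df = pd.read_csv(path, dtype=str)
    if "label" not in df.columns:
        raise FormatError(f"{path}: annotation CSV needs a 'label' column")
    cell_ids = df["cell_id"].tolist() if "cell_id" in df.columns else [
        str(i) for i in range(len(df))
    ]
    prov = df["provenance"].tolist() if "provenance" in df.columns else []
    return cell_ids, AnnotationVector(labels=df["label"].tolist(), provenance=prov)


def read_labels(path: str | Path) -> list[str]:
    """Read reference labels: a one-column (optionally headed 'label') CSV."""
    df = pd.read_csv(path, dtype=str)
    col = "label" if "label" in df.columns else df.columns[-1]
    return df[col].tolist()
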