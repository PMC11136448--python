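"""Marker tables: the gating grammar, its parser, and the signature dictionary.

A marker table gives, per cell type, a pseudo-gating strategy: each
informative marker is declared positive (``+``), medium (``m``), negative
(``-``) or free (``*``), and markers may be combined with an inclusive-or
(``|``) or exclusive-or (``^``) operator, e.g. ``CD11b+|CD11c+|`` ("CD11b or
CD11c or both") and ``CD11b+^CD11c+^`` ("one of the two, not both").
Markers of the universe that an entry does not mention are implicit
wildcards.

The table is compiled into a :class:`SignatureDictionary`: an ordered view of
every concrete per-marker level assignment each cell type admits.  When one
signature satisfies several cell types, the record defined by more ``+``/``m``
markers wins, then the record with more non-wildcard markers, then table
order.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .errors import SpecificationError

LEVELS = ("-", "m", "+")
WILDCARD = "*"

#: accepted level spellings, normalized to the canonical symbols
_LEVEL_ALIASES = {
    "+": "+", "-": "-", "m": "m", "*": "*",
    "hi": "+", "mid": "m", "lo": "-",
    "−": "-",  # unicode minus
}

_OP_NAMES = {"|": "OR", "^": "XOR"}


@dataclass(frozen=True)
class MarkerToken:
    """One atom of a gating entry: a marker, a level, and its combinator."""

    marker: str
    level: str  # one of "+", "m", "-", "*"
    operator: str = "AND"  # "AND", "OR" or "XOR"

    def __post_init__(self) -> None:
        if not self.marker:
            raise SpecificationError("marker name must be non-empty")
        if self.level not in LEVELS and self.level != WILDCARD:
            raise SpecificationError(f"invalid level {self.level!r}")
        if self.operator in ("OR", "XOR") and self.level == WILDCARD:
            raise SpecificationError(
                f"wildcard level not allowed inside an {self.operator} group "
                f"(marker {self.marker})"
            )


# a group is a run of tokens sharing one operator; AND groups are singletons
Group = tuple[MarkerToken, ...]


def _normalize_level(text: str) -> str | None:
    return _LEVEL_ALIASES.get(text)


def _parse_atom(text: str, operator: str) -> MarkerToken:
    """Parse ``CD11b+`` / ``CD3lo`` / ``CD4mid`` into a token."""
    text = text.strip()
    for suffix in ("mid", "hi", "lo"):
        if len(text) > len(suffix) and text.endswith(suffix):
            return MarkerToken(text[: -len(suffix)], _LEVEL_ALIASES[suffix], operator)
    if len(text) >= 2 and (level := _normalize_level(text[-1])) is not None:
        return MarkerToken(text[:-1], level, operator)
    raise SpecificationError(
        f"token {text!r} lacks a level symbol (+, -, m, *, hi, mid or lo)"
    )


def parse_signature_string(text: str) -> list[Group]:
    """Parse a comma-separated gating entry into operator groups.

    Within one comma-separated chunk, tokens suffixed by ``|`` form an OR
    group and tokens suffixed by ``^`` an XOR group; a chunk without
    operators is a singleton AND group.  Mixing ``|`` and ``^`` inside one
    chunk is a syntax error, as is a wildcard level inside a group.
    """
    groups: list[Group] = []
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        ops = set(re.findall(r"[|^]", chunk))
        if not ops:
            groups.append((_parse_atom(chunk, "AND"),))
            continue
        if len(ops) > 1:
            raise SpecificationError(
                f"mixed operators '|' and '^' in group {chunk!r}"
            )
        op_char = ops.pop()
        op = _OP_NAMES[op_char]
        atoms = [a for a in chunk.split(op_char) if a.strip()]
        if not atoms:
            raise SpecificationError(f"empty operator group {chunk!r}")
        groups.append(tuple(_parse_atom(a, op) for a in atoms))
    return groups


def serialize_groups(groups: Sequence[Group]) -> str:
    """Inverse of :func:`parse_signature_string`, in normalized form."""
    parts: list[str] = []
    for group in groups:
        op = group[0].operator
        if op == "AND":
            parts.append(f"{group[0].marker}{group[0].level}")
        else:
            char = "|" if op == "OR" else "^"
            parts.append("".join(f"{t.marker}{t.level}{char}" for t in group))
    return ",".join(parts)


@dataclass
class MarkerTable:
    """Ordered map from cell type to its gating entry (a list of groups)."""

    entries: dict[str, list[Group]] = field(default_factory=dict)
    marker_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        referenced: list[str] = []
        for cell_type, groups in self.entries.items():
            seen_and: dict[str, str] = {}
            for group in groups:
                ops = {t.operator for t in group}
                if len(ops) != 1:
                    raise SpecificationError(
                        f"heterogeneous operators in a group of {cell_type!r}"
                    )
                for tok in group:
                    if tok.marker not in referenced:
                        referenced.append(tok.marker)
                    if tok.operator == "AND" and tok.level != WILDCARD:
                        prev = seen_and.setdefault(tok.marker, tok.level)
                        if prev != tok.level:
                            raise SpecificationError(
                                f"contradictory levels {prev!r} and {tok.level!r} "
                                f"for marker {tok.marker} in {cell_type!r}"
                            )
        if not self.marker_universe:
            self.marker_universe = referenced
        else:
            missing = [m for m in referenced if m not in self.marker_universe]
            if missing:
                raise SpecificationError(
                    f"markers {missing} referenced but absent from the universe"
                )

    @property
    def cell_types(self) -> list[str]:
        return list(self.entries)

    def entry_string(self, cell_type: str) -> str:
        return serialize_groups(self.entries[cell_type])


def required_levels(table: MarkerTable) -> dict[str, int]:
    """Number of mixture components each marker needs: 3 iff some entry
    declares a medium level for it, else 2."""
    out = {m: 2 for m in table.marker_universe}
    for groups in table.entries.values():
        for group in groups:
            for tok in group:
                if tok.level == "m":
                    out[tok.marker] = 3
    return out


def _token_holds(tok: MarkerToken, assignment: Mapping[str, str]) -> bool:
    return tok.level == WILDCARD or assignment[tok.marker] == tok.level


def entry_predicate(groups: Sequence[Group]) -> Callable[[Mapping[str, str]], bool]:
    """Membership predicate of an entry over full-universe assignments."""

    def pred(assignment: Mapping[str, str]) -> bool:
        for group in groups:
            op = group[0].operator
            hits = sum(_token_holds(t, assignment) for t in group)
            if op == "AND":
                if hits != len(group):
                    return False
            elif op == "OR":
                if hits < 1:
                    return False
            else:  # XOR: exactly one token holds
                if hits != 1:
                    return False
        return True

    return pred


def expand_cell_type(
    groups: Sequence[Group],
    marker_universe: Sequence[str],
    levels_per_marker: Mapping[str, int],
    max_free_markers: int = 12,
) -> set[tuple[str, ...]]:
    """Materialize every concrete signature an entry admits.

    A concrete signature assigns one level to every marker of the universe.
    AND tokens fix their marker; all other markers range over their allowed
    levels ({-,+} for two-component markers, {-,m,+} for three); OR/XOR
    groups then filter the combinations.  Enumeration is capped at
    ``3**max_free_markers`` combinations — larger entries must be evaluated
    through :func:`entry_predicate` instead.
    """
    fixed: dict[str, str] = {}
    for group in groups:
        for tok in group:
            if tok.operator == "AND" and tok.level != WILDCARD:
                if tok.marker in fixed and fixed[tok.marker] != tok.level:
                    raise SpecificationError(
                        f"contradictory AND levels for marker {tok.marker}"
                    )
                fixed[tok.marker] = tok.level

    def allowed(marker: str) -> tuple[str, ...]:
        domain = ("-", "m", "+") if levels_per_marker.get(marker, 2) == 3 else ("-", "+")
        if marker in fixed:
            # a fixed level outside the marker's domain (m on a two-level
            # marker) admits nothing: the expansion is empty
            return (fixed[marker],) if fixed[marker] in domain else ()
        return domain

    n_free = sum(1 for m in marker_universe if m not in fixed)
    if n_free > max_free_markers:
        raise SpecificationError(
            f"entry leaves {n_free} markers free; refusing to enumerate more "
            f"than 3^{max_free_markers} signatures"
        )
    pred = entry_predicate(groups)
    out: set[tuple[str, ...]] = set()
    for combo in itertools.product(*(allowed(m) for m in marker_universe)):
        if pred(dict(zip(marker_universe, combo))):
            out.add(combo)
    return out


def _entry_priority(groups: Sequence[Group], order_index: int) -> tuple[int, int, int]:
    """(count of +/m tokens, count of non-wildcard tokens, table order)."""
    plus_m = sum(1 for g in groups for t in g if t.level in ("+", "m"))
    nonwild = sum(1 for g in groups for t in g if t.level != WILDCARD)
    return (plus_m, nonwild, order_index)


@dataclass
class SignatureDictionary:
    """Priority-ordered view of a marker table's concrete signatures.

    Entries are kept as predicates and evaluated lazily; :attr:`records`
    materializes the per-signature dictionary for small universes (used by
    brute-force checks and tiny tables).
    """

    table: MarkerTable
    levels_per_marker: dict[str, int]
    # (cell_type, predicate, priority_key), sorted best-first
    _ordered: list[tuple[str, Callable[[Mapping[str, str]], bool], tuple[int, int, int]]] = field(
        default_factory=list, repr=False
    )

    @classmethod
    def from_table(
        cls, table: MarkerTable, levels_per_marker: Mapping[str, int] | None = None
    ) -> "SignatureDictionary":
        levels = dict(levels_per_marker) if levels_per_marker else required_levels(table)
        ordered = []
        for idx, (cell_type, groups) in enumerate(table.entries.items()):
            ordered.append(
                (cell_type, entry_predicate(groups), _entry_priority(groups, idx))
            )
        # higher +/m count first, then more constrained, then table order
        ordered.sort(key=lambda rec: (-rec[2][0], -rec[2][1], rec[2][2]))
        return cls(table=table, levels_per_marker=levels, _ordered=ordered)

    @property
    def marker_universe(self) -> list[str]:
        return self.table.marker_universe

    def lookup(self, signature: Mapping[str, str]) -> str | None:
        """Cell type of the best-priority entry the signature satisfies."""
        for cell_type, pred, _ in self._ordered:
            if pred(signature):
                return cell_type
        return None

    def records(self) -> list[tuple[tuple[str, ...], str, tuple[int, int, int]]]:
        """Materialized (signature, cell_type, priority) list, best-first;
        a signature appears once per cell type whose entry admits it."""
        out = []
        for cell_type, _, priority in self._ordered:
            for sig in expand_cell_type(
                self.table.entries[cell_type], self.marker_universe, self.levels_per_marker
            ):
                out.append((sig, cell_type, priority))
        return out

    def empty_expansions(self) -> list[str]:
        """Cell types whose entry admits no signature (e.g. unsatisfiable XOR)."""
        flagged = []
        for cell_type, groups in self.table.entries.items():
            try:
                if not expand_cell_type(groups, self.marker_universe, self.levels_per_marker):
                    flagged.append(cell_type)
            except SpecificationError:
                continue  # too large to enumerate — cannot be empty cheaply
        return flagged


def build_dictionary(
    table: MarkerTable, levels_per_marker: Mapping[str, int] | None = None
) -> SignatureDictionary:
    """Compile a marker table into its priority-ordered signature dictionary."""
    if not table.entries:
        raise SpecificationError("marker table has no entries")
    return SignatureDictionary.from_table(table, levels_per_marker)


def table_from_strings(entries: Mapping[str, str], marker_universe: Iterable[str] | None = None) -> MarkerTable:
    """Convenience constructor: cell type -> compact signature string."""
    parsed = {ct: parse_signature_string(s) for ct, s in entries.items()}
    return MarkerTable(entries=parsed, marker_universe=list(marker_universe or []))
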