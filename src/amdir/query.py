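"""Headless table filtering, sample→library joins, and selection summaries.

Reproduces the interactive viewer's filtering semantics without a browser:
per-column predicate chains combined left-to-right with explicit AND/OR
connectives, with the chains of different columns combined with AND.  The
worked example — host-associated samples published since 2020 from Spain —
is therefore the expression ``publication_year>=2020 & geo_loc_name=Spain``,
equivalent to the shell one-liner
``awk -F "\\t" 'NR==1 || $2 >= 2020 && $7 == "Spain"'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import UsageError
from .schema_model import (
    LIST_SEPARATOR,
    MISSING_TOKEN,
    MetadataTable,
)
from .validation import library_sample_key

_NUMERIC_OPS = frozenset({"lt", "le", "gt", "ge"})
_OPS = frozenset({"eq", "ne", "lt", "le", "gt", "ge", "contains", "in_set"})


@dataclass(frozen=True)
class Predicate:
    """One comparison against one column.

    Numeric operators parse the cell as a number; cells holding the
    missing-data token (or anything unparseable) never satisfy them.
    ``contains`` is a case-sensitive substring test.
    """

    column: str
    op: str
    operand: object  # str | float | frozenset[str]

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise UsageError(f"unknown predicate operator {self.op!r}")

    def matches(self, cell: str) -> bool:
        if self.op in _NUMERIC_OPS:
            if cell == MISSING_TOKEN:
                return False
            try:
                value = float(cell)
                bound = float(self.operand)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                return False
            return {
                "lt": value < bound,
                "le": value <= bound,
                "gt": value > bound,
                "ge": value >= bound,
            }[self.op]
        if self.op == "eq":
            return cell == str(self.operand)
        if self.op == "ne":
            return cell != str(self.operand)
        if self.op == "contains":
            return str(self.operand) in cell
        if self.op == "in_set":
            return cell in self.operand  # type: ignore[operator]
        raise AssertionError(self.op)


@dataclass(frozen=True)
class FilterExpression:
    """Clauses ``(predicate, connective)`` with connective in {"AND", "OR"}.

    Within one column, clauses chain left-to-right through their
    connectives (the first clause's connective is ignored); the per-column
    results are then combined with AND.  An empty expression selects all
    rows.
    """

    clauses: tuple[tuple[Predicate, str], ...] = ()

    def __post_init__(self) -> None:
        for _, conn in self.clauses:
            if conn not in ("AND", "OR"):
                raise UsageError(f"connective must be AND or OR, got {conn!r}")

    @property
    def columns(self) -> list[str]:
        seen: list[str] = []
        for pred, _ in self.clauses:
            if pred.column not in seen:
                seen.append(pred.column)
        return seen

    def matches_row(self, row: Sequence[str], header: Sequence[str]) -> bool:
        index = {name: i for i, name in enumerate(header)}
        for col in self.columns:
            result: bool | None = None
            for pred, conn in self.clauses:
                if pred.column != col:
                    continue
                hit = pred.matches(row[index[col]])
                if result is None:
                    result = hit
                elif conn == "AND":
                    result = result and hit
                else:
                    result = result or hit
            if not result:
                return False
        return True


def filter_table(table: MetadataTable, expr: FilterExpression) -> MetadataTable:
    """Keep exactly the rows satisfying ``expr``; header and order preserved."""
    for col in expr.columns:
        if col not in table.header:
            raise UsageError(
                f"filter references unknown column {col!r}; columns: {table.header}"
            )
    kept = [row for row in table.rows if expr.matches_row(row, table.header)]
    return MetadataTable(
        list(table.header), [list(r) for r in kept], table.provenance, table.schema
    )


def join_libraries(
    samples_subset: MetadataTable, libraries: MetadataTable
) -> MetadataTable:
    """Library rows whose sample linkage key matches a retained sample.

    Uses the validation module's linkage rule (archive sample accession when
    present, else exact sample-name match); library row order is preserved.
    """
    if samples_subset.schema is None or libraries.schema is None:
        raise UsageError("join_libraries requires schema-bound tables")
    if samples_subset.schema.dataset_kind != libraries.schema.dataset_kind:
        raise UsageError("samples and libraries belong to different dataset kinds")
    accessions: set[str] = set()
    names: set[str] = set()
    if "archive_accession" in samples_subset.header:
        idx = samples_subset.column_index("archive_accession")
        for row in samples_subset.rows:
            accessions.update(row[idx].split(LIST_SEPARATOR))
    name_idx = samples_subset.column_index("sample_name")
    for row in samples_subset.rows:
        names.add(row[name_idx])
    kept = []
    for row in libraries.rows:
        mode, keys = library_sample_key(row, libraries)
        pool = accessions if mode == "accession" else names
        if any(k in pool for k in keys):
            kept.append(list(row))
    return MetadataTable(
        list(libraries.header), kept, libraries.provenance, libraries.schema
    )


@dataclass(frozen=True)
class SelectionSummary:
    """Row/run counts and total download size of a library selection."""

    n_rows: int
    n_runs: int
    total_bytes: int

    def human_size(self) -> str:
        size = float(self.total_bytes)
        for unit in ("B", "KB", "MB", "GB", "TB"):
            if size < 1024 or unit == "TB":
                return f"{size:.1f} {unit}"
            size /= 1024
        raise AssertionError


def summarize_selection(libraries: MetadataTable) -> SelectionSummary:
    """Counts and the exact total bytes a download of the selection would use."""
    size_idx = libraries.column_index("download_sizes")
    run_idx = libraries.column_index("archive_data_accession")
    total = 0
    n_runs = 0
    for i, row in enumerate(libraries.rows):
        n_runs += sum(1 for t in row[run_idx].split(LIST_SEPARATOR) if t)
        cell = row[size_idx]
        if cell == "":
            continue
        for token in cell.split(LIST_SEPARATOR):
            try:
                total += int(token)
            except ValueError:
                raise UsageError(
                    f"line {i + 2}: download size {token!r} is not an integer"
                ) from None
    return SelectionSummary(len(libraries.rows), n_runs, total)


# ---------------------------------------------------------------------------
# Expression string syntax (CLI convenience)
# ---------------------------------------------------------------------------

_STRING_OPS = (
    (">=", "ge"),
    ("<=", "le"),
    ("!=", "ne"),
    ("~", "contains"),
    (">", "gt"),
    ("<", "lt"),
    ("=", "eq"),
)


def parse_expression(text: str) -> FilterExpression:
    """Parse the tiny CLI filter syntax into a :class:`FilterExpression`.

    Clauses are separated by ``&`` (AND) or ``|`` (OR); each clause is
    ``column OP value`` with OP one of ``= != >= <= > < ~`` (``~`` is
    substring containment).  Values are taken verbatim after stripping
    surrounding whitespace and optional single/double quotes.  Example::

        geo_loc_name=Spain & publication_year>=2020
    """
    text = text.strip()
    if not text:
        return FilterExpression()
    clauses: list[tuple[Predicate, str]] = []
    parts: list[tuple[str, str]] = []  # (connective, clause text)
    current_conn = "AND"
    buf = ""
    for ch in text:
        if ch in "&|":
            parts.append((current_conn, buf))
            current_conn = "AND" if ch == "&" else "OR"
            buf = ""
        else:
            buf += ch
    parts.append((current_conn, buf))
    for connective, clause in parts:
        clause = clause.strip()
        if not clause:
            raise UsageError(f"empty clause in filter expression {text!r}")
        for sym, op in _STRING_OPS:
            if sym in clause:
                column, _, raw = clause.partition(sym)
                column = column.strip()
                value = raw.strip().strip("'\"")
                if not column:
                    raise UsageError(f"clause {clause!r} lacks a column name")
                operand: object = value
                if op in _NUMERIC_OPS:
                    try:
                        operand = float(value)
                    except ValueError:
                        raise UsageError(
                            f"operator {sym!r} needs a numeric value, got {value!r}"
                        ) from None
                clauses.append((Predicate(column, op, operand), connective))
                break
        else:
            raise UsageError(
                f"clause {clause!r} has no operator (expected one of = != >= <= > < ~)"
            )
    return FilterExpression(tuple(clauses))
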