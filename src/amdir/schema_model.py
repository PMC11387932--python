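"""Table dialect, schemas, and vocabularies for ancient-metagenome metadata.

The directory distributes its metadata as plain TSV tables (samples and
libraries) for each of three dataset categories, validated against JSON
schema documents with JSON "enum" vocabulary files for controlled fields.
This module defines the dialect and the in-memory carriers:

* :class:`MetadataTable` — an ordered header plus rows of string cells;
* :class:`TableSchema` / :class:`ColumnSpec` — positional column contracts;
* :class:`EnumVocabulary` — a named controlled vocabulary;
* :class:`ReleaseTag` — a dated, chronologically comparable release label.

The TSV dialect is deliberately rigid so that serialisation is byte-stable:
UTF-8, LF line endings, tab separator, no quoting or escaping (tabs and
newlines are forbidden inside cells), a mandatory header row, and a trailing
newline.  ``write_table(read_table(x)) == x`` holds for every conforming
file, which keeps version-control diffs of curated tables minimal.
"""

from __future__ import annotations

import json
import re
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import (
    ReleaseNotFoundError,
    SchemaBindingError,
    SchemaConsistencyError,
    SerializationError,
    TableParseError,
    TransportError,
    UsageError,
)

#: Canonical missing-data token for categorical/enum cells where allowed.
MISSING_TOKEN = "unknown"

VALUE_KINDS = frozenset(
    {
        "free_text",
        "integer",
        "number",
        "doi",
        "accession_list",
        "url_list",
        "md5_list",
        "byte_size_list",
        "enum",
    }
)

#: Separator inside list-valued cells (URLs, md5s, sizes, accessions),
#: following the sequencing archives' multi-file field convention.
LIST_SEPARATOR = ";"


# ---------------------------------------------------------------------------
# Dataset kinds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetKind:
    """One of the directory's dataset categories.

    ``identifier`` is the stable programmatic name; ``dir_name`` is the
    canonical directory string used in release assets and on the command
    line (e.g. ``ancientmetagenome-hostassociated``).
    """

    identifier: str
    dir_name: str


HOST_ASSOCIATED_METAGENOME = DatasetKind(
    "host_associated_metagenome", "ancientmetagenome-hostassociated"
)
HOST_ASSOCIATED_SINGLEGENOME = DatasetKind(
    "host_associated_singlegenome", "ancientsinglegenome-hostassociated"
)
ENVIRONMENTAL_METAGENOME = DatasetKind(
    "environmental_metagenome", "ancientmetagenome-environmental"
)

#: Registry of known dataset kinds, keyed by identifier.  Mutable so a
#: deployment tracking a renamed upstream directory can override entries.
DATASET_KINDS: dict[str, DatasetKind] = {
    k.identifier: k
    for k in (
        HOST_ASSOCIATED_METAGENOME,
        HOST_ASSOCIATED_SINGLEGENOME,
        ENVIRONMENTAL_METAGENOME,
    )
}


def dataset_kind_from_identifier(identifier: str) -> DatasetKind:
    try:
        return DATASET_KINDS[identifier]
    except KeyError:
        raise UsageError(
            f"unknown dataset kind {identifier!r}; known: {sorted(DATASET_KINDS)}"
        ) from None


def dataset_kind_from_dir_name(dir_name: str) -> DatasetKind:
    for kind in DATASET_KINDS.values():
        if kind.dir_name == dir_name:
            return kind
    known = sorted(k.dir_name for k in DATASET_KINDS.values())
    raise UsageError(f"unknown table directory {dir_name!r}; known: {known}")


# ---------------------------------------------------------------------------
# Release tags
# ---------------------------------------------------------------------------

_RELEASE_RE = re.compile(r"^v(\d{2})\.(\d{2})(?:\.(\d+))?$")


@dataclass(frozen=True, order=False)
class ReleaseTag:
    """A release label of the form ``v<YY>.<MM>[.<patch>]``, e.g. ``v24.03.0``."""

    tag: str

    def __post_init__(self) -> None:
        if not _RELEASE_RE.match(self.tag):
            raise UsageError(
                f"release tag {self.tag!r} does not match v<YY>.<MM>[.<patch>]"
            )

    @property
    def _parts(self) -> tuple[int, int, int]:
        m = _RELEASE_RE.match(self.tag)
        assert m is not None
        return (int(m.group(1)), int(m.group(2)), int(m.group(3) or 0))

    @property
    def year(self) -> int:
        return self._parts[0]

    @property
    def month(self) -> int:
        return self._parts[1]

    @property
    def patch(self) -> int:
        return self._parts[2]

    def __lt__(self, other: "ReleaseTag") -> bool:
        return self._parts < other._parts

    def __le__(self, other: "ReleaseTag") -> bool:
        return self._parts <= other._parts

    def __str__(self) -> str:
        return self.tag


# ---------------------------------------------------------------------------
# Schema types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnSpec:
    """Contract for one table column.

    ``position`` is 1-based and mirrors the column's place in the header,
    so shell one-liners addressing columns by number (awk ``$2``, ``$7``)
    stay valid across toolkit and hand curation.
    """

    name: str
    position: int
    required: bool = True
    value_kind: str = "free_text"
    enum_ref: str = ""
    missing_token_allowed: bool = False

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise SchemaConsistencyError(
                f"column {self.name!r}: unknown value_kind {self.value_kind!r}"
            )
        if (self.value_kind == "enum") != bool(self.enum_ref):
            raise SchemaConsistencyError(
                f"column {self.name!r}: enum_ref must be set iff value_kind is 'enum'"
            )


@dataclass(frozen=True)
class EnumVocabulary:
    """A named controlled vocabulary (ordered, unique, non-empty tokens)."""

    name: str
    values: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.values)) != len(self.values):
            raise SchemaConsistencyError(f"vocabulary {self.name!r} has duplicate tokens")
        if any(not v for v in self.values):
            raise SchemaConsistencyError(f"vocabulary {self.name!r} has empty tokens")

    def __contains__(self, token: str) -> bool:
        return token in self.values


@dataclass(frozen=True)
class TableSchema:
    """Column contracts for one (dataset kind, table type) pair."""

    dataset_kind: DatasetKind
    table_type: str  # "samples" | "libraries"
    columns: tuple[ColumnSpec, ...]
    key_columns: tuple[str, ...]
    enums: Mapping[str, EnumVocabulary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table_type not in ("samples", "libraries"):
            raise SchemaConsistencyError(
                f"table_type must be 'samples' or 'libraries', got {self.table_type!r}"
            )
        if not self.columns:
            raise SchemaConsistencyError("schema declares zero columns")
        positions = sorted(c.position for c in self.columns)
        if positions != list(range(1, len(self.columns) + 1)):
            raise SchemaConsistencyError(
                "column positions are not a contiguous 1..N permutation"
            )
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaConsistencyError("duplicate column names in schema")
        for col in self.columns:
            if col.enum_ref and col.enum_ref not in self.enums:
                raise SchemaConsistencyError(
                    f"column {col.name!r} references unknown vocabulary {col.enum_ref!r}"
                )
        missing_keys = set(self.key_columns) - set(names)
        if missing_keys:
            raise SchemaConsistencyError(
                f"key columns not in schema: {sorted(missing_keys)}"
            )

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in sorted(self.columns, key=lambda c: c.position))

    def column(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise UsageError(f"schema has no column {name!r}")

    def vocabulary(self, col: ColumnSpec) -> EnumVocabulary:
        return self.enums[col.enum_ref]


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------


@dataclass
class MetadataTable:
    """An ordered header plus rows of string cells.

    The universal carrier for sample and library tables.  Cells are always
    strings; numeric interpretation happens at the point of use (validation,
    filtering) so the table round-trips byte-exactly through the dialect.

    ``line number`` convention throughout the toolkit: 1-based counting the
    header as line 1, so data row ``i`` (0-based) is line ``i + 2`` — what a
    user sees in a text editor.
    """

    header: list[str]
    rows: list[list[str]]
    provenance: str = ""
    schema: TableSchema | None = None

    def __post_init__(self) -> None:
        ncol = len(self.header)
        for i, row in enumerate(self.rows):
            if len(row) != ncol:
                raise TableParseError(
                    f"row at line {i + 2} has {len(row)} cells, expected {ncol}",
                    line=i + 2,
                )
        if self.schema is not None:
            _check_header(self.header, self.schema)

    def column_index(self, name: str) -> int:
        try:
            return self.header.index(name)
        except ValueError:
            raise UsageError(
                f"table has no column {name!r}; columns: {self.header}"
            ) from None

    def column(self, name: str) -> list[str]:
        idx = self.column_index(name)
        return [row[idx] for row in self.rows]

    def cell(self, line: int, name: str) -> str:
        """Cell by editor line number (first data row = line 2)."""
        return self.rows[line - 2][self.column_index(name)]

    def bind(self, schema: TableSchema) -> "MetadataTable":
        """Return the same table bound to ``schema`` (header must match)."""
        _check_header(self.header, schema)
        return MetadataTable(self.header, self.rows, self.provenance, schema)

    def to_pandas(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.header, dtype=str)

    def __len__(self) -> int:
        return len(self.rows)


def _check_header(header: Sequence[str], schema: TableSchema) -> None:
    expected = list(schema.column_names)
    if list(header) == expected:
        return
    missing = [c for c in expected if c not in header]
    extra = [c for c in header if c not in expected]
    reordered = (
        sorted(header) == sorted(expected) and list(header) != expected
    )
    parts = []
    if missing:
        parts.append(f"missing columns {missing}")
    if extra:
        parts.append(f"extra columns {extra}")
    if reordered:
        parts.append("columns are present but out of order")
    raise SchemaBindingError(
        "header does not match schema "
        f"({schema.dataset_kind.identifier}/{schema.table_type}): "
        + "; ".join(parts or ["header mismatch"])
    )


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------


def read_table(
    tsv: bytes | str,
    schema: TableSchema | None = None,
    provenance: str = "",
) -> MetadataTable:
    """Parse TSV text into a :class:`MetadataTable`.

    The first line is the header; each subsequent non-empty line is one row.
    Ragged rows are rejected with their 1-based line number.  When a schema
    is given the header must match its column names exactly and in order.
    """
    if isinstance(tsv, bytes):
        try:
            text = tsv.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise TableParseError(f"input is not valid UTF-8: {exc}") from exc
    else:
        text = tsv
    if not text:
        raise TableParseError("empty input: missing header row")
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()  # trailing newline
    header = lines[0].split("\t")
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise TableParseError(
                f"line {lineno}: expected {len(header)} tab-separated fields, "
                f"found {len(cells)}",
                line=lineno,
            )
        rows.append(cells)
    table = MetadataTable(header, rows, provenance=provenance)
    if schema is not None:
        table = table.bind(schema)
    return table


def write_table(table: MetadataTable) -> str:
    """Serialise to the dialect: tabs, LF, trailing newline, no quoting."""
    out_lines = ["\t".join(table.header)]
    for i, row in enumerate(table.rows):
        for j, cell in enumerate(row):
            if "\t" in cell or "\n" in cell or "\r" in cell:
                raise SerializationError(
                    f"cell at line {i + 2}, column {table.header[j]!r} contains "
                    "a tab or newline, which the dialect forbids"
                )
        out_lines.append("\t".join(row))
    return "\n".join(out_lines) + "\n"


def write_table_file(table: MetadataTable, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(write_table(table), encoding="utf-8", newline="")
    return path


def read_table_file(
    path: str | Path, schema: TableSchema | None = None
) -> MetadataTable:
    path = Path(path)
    return read_table(path.read_bytes(), schema=schema, provenance=str(path))


# ---------------------------------------------------------------------------
# Schema documents
# ---------------------------------------------------------------------------


def load_enum(name: str, document: str) -> EnumVocabulary:
    """Parse one JSON vocabulary file (a bare array of tokens)."""
    try:
        data = json.loads(document)
    except json.JSONDecodeError as exc:
        raise TableParseError(f"vocabulary {name!r}: malformed JSON: {exc}") from exc
    if not isinstance(data, list) or not all(isinstance(v, str) for v in data):
        raise SchemaConsistencyError(
            f"vocabulary {name!r} must be a JSON array of strings"
        )
    return EnumVocabulary(name, tuple(data))


def load_schema(schema_document: str, enums: Mapping[str, str]) -> TableSchema:
    """Build a :class:`TableSchema` from a JSON document plus vocabulary files.

    The document declares ``dataset_kind``, ``table_type``, ``key_columns``
    and an ordered ``columns`` array; column position is the 1-based index
    in that array.  Every ``enum_ref`` must resolve among ``enums`` —
    dangling references are fatal.
    """
    try:
        doc = json.loads(schema_document)
    except json.JSONDecodeError as exc:
        raise TableParseError(f"schema document: malformed JSON: {exc}") from exc
    for key in ("dataset_kind", "table_type", "columns"):
        if key not in doc:
            raise SchemaConsistencyError(f"schema document lacks {key!r}")
    kind = dataset_kind_from_identifier(doc["dataset_kind"])
    vocabularies = {name: load_enum(name, text) for name, text in enums.items()}
    columns = []
    for i, cdoc in enumerate(doc["columns"], start=1):
        if "name" not in cdoc:
            raise SchemaConsistencyError(f"column at position {i} lacks a name")
        columns.append(
            ColumnSpec(
                name=cdoc["name"],
                position=i,
                required=bool(cdoc.get("required", True)),
                value_kind=cdoc.get("value_kind", "free_text"),
                enum_ref=cdoc.get("enum_ref", ""),
                missing_token_allowed=bool(cdoc.get("missing_token_allowed", False)),
            )
        )
    needed = {c.enum_ref for c in columns if c.enum_ref}
    dangling = needed - set(vocabularies)
    if dangling:
        raise SchemaConsistencyError(
            f"schema references vocabularies not supplied: {sorted(dangling)}"
        )
    return TableSchema(
        dataset_kind=kind,
        table_type=doc["table_type"],
        columns=tuple(columns),
        key_columns=tuple(doc.get("key_columns", ())),
        enums=vocabularies,
    )


def _resource_text(subdir: str, filename: str) -> str:
    ref = _importlib_resources.files("amdir") / "resources" / subdir / filename
    return ref.read_text(encoding="utf-8")


def builtin_enum_documents() -> dict[str, str]:
    """All shipped vocabulary files, keyed by vocabulary name."""
    root = _importlib_resources.files("amdir") / "resources" / "enums"
    docs = {}
    for entry in root.iterdir():
        if entry.name.endswith(".json"):
            docs[entry.name[: -len(".json")]] = entry.read_text(encoding="utf-8")
    return docs


def builtin_schema(kind: DatasetKind, table_type: str) -> TableSchema:
    """Load a shipped schema (schemas are data, not code)."""
    if table_type not in ("samples", "libraries"):
        raise UsageError(f"table_type must be 'samples' or 'libraries', got {table_type!r}")
    filename = f"{kind.identifier}_{table_type}.json"
    try:
        document = _resource_text("schemas", filename)
    except FileNotFoundError:
        raise SchemaConsistencyError(f"no shipped schema {filename}") from None
    return load_schema(document, builtin_enum_documents())


def load_schema_dir(schema_dir: str | Path, kind: DatasetKind, table_type: str) -> TableSchema:
    """Load a schema from an on-disk directory laid out like the resources."""
    schema_dir = Path(schema_dir)
    doc_path = schema_dir / "schemas" / f"{kind.identifier}_{table_type}.json"
    if not doc_path.exists():
        raise SchemaConsistencyError(f"no schema document at {doc_path}")
    enums = {
        p.stem: p.read_text(encoding="utf-8")
        for p in sorted((schema_dir / "enums").glob("*.json"))
    }
    return load_schema(doc_path.read_text(encoding="utf-8"), enums)


# ---------------------------------------------------------------------------
# Release-table retrieval
# ---------------------------------------------------------------------------

#: Default base URL for release assets; configuration, not contract.
DEFAULT_RELEASE_BASE_URL = (
    "https://github.com/SPAAM-community/AncientMetagenomeDir/releases/download"
)


def release_asset_name(kind: DatasetKind, table_type: str, release: ReleaseTag) -> str:
    return f"{kind.dir_name}_{table_type}_{release.tag}.tsv"


@dataclass(frozen=True)
class LocalReleaseSource:
    """A directory mirroring the release layout (flat files by asset name)."""

    directory: Path

    def fetch(self, kind: DatasetKind, table_type: str, release: ReleaseTag) -> tuple[bytes, str]:
        path = Path(self.directory) / release_asset_name(kind, table_type, release)
        if not path.exists():
            raise ReleaseNotFoundError(
                f"release {release.tag} has no asset {path.name} under {self.directory}"
            )
        return path.read_bytes(), str(path)


@dataclass(frozen=True)
class RemoteReleaseSource:
    """HTTPS retrieval of release assets from a configurable base URL."""

    base_url: str = DEFAULT_RELEASE_BASE_URL
    timeout: float = 30.0

    def fetch(self, kind: DatasetKind, table_type: str, release: ReleaseTag) -> tuple[bytes, str]:
        url = f"{self.base_url}/{release.tag}/{release_asset_name(kind, table_type, release)}"
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                return resp.read(), url
        except urllib.error.HTTPError as exc:
            if exc.code == 404:
                raise ReleaseNotFoundError(
                    f"release {release.tag}: no asset at {url} (HTTP 404)"
                ) from exc
            raise TransportError(
                f"fetching {url} failed with HTTP {exc.code}", status=exc.code
            ) from exc
        except (urllib.error.URLError, OSError, TimeoutError) as exc:
            raise TransportError(f"fetching {url} failed: {exc}") from exc


def resolve_release_table(
    kind: DatasetKind,
    table_type: str,
    release: ReleaseTag | str,
    source: LocalReleaseSource | RemoteReleaseSource | None = None,
    bind_schema: bool = True,
) -> MetadataTable:
    """Fetch and parse one released table.

    ``source`` defaults to the remote release host.  Transport failures and
    parse failures raise distinct error types so callers can retry one and
    not the other.
    """
    if isinstance(release, str):
        release = ReleaseTag(release)
    if source is None:
        source = RemoteReleaseSource()
    payload, origin = source.fetch(kind, table_type, release)
    schema = builtin_schema(kind, table_type) if bind_schema else None
    return read_table(payload, schema=schema, provenance=origin)
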