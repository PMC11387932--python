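"""Dataset validation: per-cell schema checks, duplication, DOIs, accessions.

Checks never raise on bad *data* — every defect becomes a
:class:`ValidationError` collected in a :class:`ValidationReport`, so a
curator reviewing a submission sees all problems in one pass, each with the
type of error, its line and column, a one-sentence explanation and a fix
hint.  Exceptions are reserved for misuse (missing columns, unbound schemas).

Check order within a cell is type → enum → pattern, and each cell reports at
most one error to avoid cascading noise.  Cross-cutting value kinds are
owned by a single check: DOI syntax by :func:`check_doi`, accession patterns
and relationships by :func:`check_accessions`.  The per-cell schema pass
leaves them alone so one bad cell never produces two report rows.

Line numbers are 1-based counting the header as line 1 (first data row is
line 2), matching what a user sees in a text editor.
"""

from __future__ import annotations

import re
import urllib.error
import urllib.request
from dataclasses import dataclass, field

from .errors import TableParseError, UsageError
from .schema_model import (
    LIST_SEPARATOR,
    MISSING_TOKEN,
    MetadataTable,
    TableSchema,
)

ERROR_TYPES = (
    "schema_violation",
    "enum_violation",
    "duplicate_row",
    "duplicate_accession",
    "invalid_doi",
    "invalid_accession",
    "accession_project_mismatch",
    "orphan_library",
    "header_mismatch",
    "structural",
)

#: DOI syntax per the registration agency's directory-indicator convention.
DOI_PATTERN = re.compile(r"^10\.\d{4,9}/\S+$", re.IGNORECASE)

# INSDC accession namespaces (project / biosample / run).  Kept as module
# config so the patterns can evolve with the archives.
PROJECT_ACCESSION_PATTERN = re.compile(r"^PRJ[EDN][A-Z]\d+$")
BIOSAMPLE_ACCESSION_PATTERN = re.compile(r"^SAM(EA|N|D)\w?\d+$")
RUN_ACCESSION_PATTERN = re.compile(r"^[EDS]RR\d{6,}$")

_INT_RE = re.compile(r"^-?\d+$")
_NUMBER_RE = re.compile(r"^-?\d+(\.\d+)?([eE][+-]?\d+)?$")
_URL_RE = re.compile(r"^(https?|ftp)://\S+$")
_MD5_RE = re.compile(r"^[0-9a-f]{32}$")
_BYTES_RE = re.compile(r"^\d+$")


@dataclass(frozen=True)
class ValidationError:
    """One defect at one location.

    ``col_pos`` is the 1-based position of ``column`` in its table header
    (0 for row- or table-scoped errors); it exists only to give reports a
    stable (table, line, column-position) ordering.
    """

    error_type: str
    table_name: str
    line: int
    column: str
    message: str
    suggestion: str
    col_pos: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.error_type not in ERROR_TYPES:
            raise UsageError(f"unknown error_type {self.error_type!r}")
        if not self.message or not self.suggestion:
            raise UsageError("message and suggestion must be non-empty")

    @property
    def location(self) -> tuple[str, int, str]:
        return (self.table_name, self.line, self.column)


@dataclass
class ValidationReport:
    """Ordered collection of validation errors; ``passed`` iff empty."""

    errors: list[ValidationError] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.errors

    def add(self, error: ValidationError) -> None:
        self.errors.append(error)

    def extend(self, other: "ValidationReport") -> "ValidationReport":
        self.errors.extend(other.errors)
        self.warnings.extend(other.warnings)
        return self

    def sorted(self) -> "ValidationReport":
        ordered = sorted(
            self.errors, key=lambda e: (e.table_name, e.line, e.col_pos, e.error_type)
        )
        return ValidationReport(ordered, list(self.warnings))

    def to_tsv(self) -> str:
        lines = ["error_type\ttable\tline\tcolumn\tmessage\tsuggestion"]
        for e in self.errors:
            lines.append(
                f"{e.error_type}\t{e.table_name}\t{e.line}\t{e.column}"
                f"\t{e.message}\t{e.suggestion}"
            )
        return "\n".join(lines) + "\n"

    def to_text(self) -> str:
        if self.passed:
            return "All checks passed.\n"
        header = ("error_type", "table", "line", "column", "message", "suggestion")
        rows = [
            (e.error_type, e.table_name, str(e.line), e.column, e.message, e.suggestion)
            for e in self.errors
        ]
        widths = [
            max(len(header[i]), *(len(r[i]) for r in rows)) for i in range(len(header))
        ]
        fmt = "  ".join(f"{{:<{w}}}" for w in widths)
        out = [fmt.format(*header)]
        out.extend(fmt.format(*r) for r in rows)
        return "\n".join(out) + "\n"


def _require_schema(table: MetadataTable, schema: TableSchema | None) -> TableSchema:
    schema = schema or table.schema
    if schema is None:
        raise UsageError("operation requires a schema-bound table")
    return schema


def _table_name(table: MetadataTable, schema: TableSchema | None) -> str:
    if schema is not None:
        return schema.table_type
    if table.schema is not None:
        return table.schema.table_type
    return table.provenance or "table"


def _split_list(cell: str) -> list[str]:
    return cell.split(LIST_SEPARATOR)


# ---------------------------------------------------------------------------
# Per-cell schema validation
# ---------------------------------------------------------------------------


def _check_cell(cell, col, schema):
    """Return (error_type, message, suggestion) or None. One error max."""
    if cell == "":
        if col.required:
            return (
                "schema_violation",
                f"required column '{col.name}' is empty",
                f"fill in a value for '{col.name}' or use '{MISSING_TOKEN}' where permitted",
            )
        return None
    kind = col.value_kind
    if kind == "enum":
        vocab = schema.vocabulary(col)
        if cell not in vocab:
            allowed = ", ".join(vocab.values)
            return (
                "enum_violation",
                f"'{cell}' is not an allowed value for '{col.name}'",
                f"use one of: {allowed}",
            )
        return None
    if cell == MISSING_TOKEN:
        if col.missing_token_allowed:
            return None
        return (
            "schema_violation",
            f"column '{col.name}' does not permit the missing-data token '{MISSING_TOKEN}'",
            f"provide a concrete {kind} value for '{col.name}'",
        )
    if kind == "integer" and not _INT_RE.match(cell):
        return (
            "schema_violation",
            f"'{cell}' is not an integer in column '{col.name}'",
            "use a whole number without separators",
        )
    if kind == "number" and not _NUMBER_RE.match(cell):
        return (
            "schema_violation",
            f"'{cell}' is not a number in column '{col.name}'",
            "use a plain decimal number",
        )
    if kind == "url_list":
        for token in _split_list(cell):
            if not _URL_RE.match(token):
                return (
                    "schema_violation",
                    f"'{token}' is not a URL in column '{col.name}'",
                    f"use http(s)/ftp URLs separated by '{LIST_SEPARATOR}'",
                )
    if kind == "md5_list":
        for token in _split_list(cell):
            if not _MD5_RE.match(token):
                return (
                    "schema_violation",
                    f"'{token}' is not an md5 checksum in column '{col.name}'",
                    "use 32 lowercase hexadecimal characters per file",
                )
    if kind == "byte_size_list":
        for token in _split_list(cell):
            if not _BYTES_RE.match(token):
                return (
                    "schema_violation",
                    f"'{token}' is not a byte count in column '{col.name}'",
                    "use non-negative integers, one per file",
                )
    if kind == "accession_list":
        for token in _split_list(cell):
            if not token:
                return (
                    "schema_violation",
                    f"empty accession token in column '{col.name}'",
                    f"remove stray '{LIST_SEPARATOR}' separators",
                )
    # doi syntax is owned by check_doi; free_text has no further constraints
    return None


def validate_schema(
    table: MetadataTable, schema: TableSchema | None = None
) -> ValidationReport:
    """Check every cell against its column contract.

    Each violating cell yields exactly one error; DOI syntax and accession
    patterns are deferred to their dedicated checks.
    """
    schema = _require_schema(table, schema)
    name = _table_name(table, schema)
    report = ValidationReport()
    cols = [schema.column(h) for h in table.header]
    for i, row in enumerate(table.rows):
        line = i + 2
        for pos, (cell, col) in enumerate(zip(row, cols), start=1):
            found = _check_cell(cell, col, schema)
            if found:
                etype, msg, hint = found
                report.add(
                    ValidationError(etype, name, line, col.name, msg, hint, col_pos=pos)
                )
    return report.sorted()


# ---------------------------------------------------------------------------
# Duplication
# ---------------------------------------------------------------------------


def check_duplicates(
    table: MetadataTable, schema: TableSchema | None = None
) -> ValidationReport:
    """Flag rows whose key tuple repeats an earlier row (on the later line)."""
    schema = _require_schema(table, schema)
    name = _table_name(table, schema)
    key_idx = [table.column_index(k) for k in schema.key_columns]
    report = ValidationReport()
    seen: dict[tuple[str, ...], int] = {}
    for i, row in enumerate(table.rows):
        line = i + 2
        key = tuple(row[j] for j in key_idx)
        if key in seen:
            keystr = ", ".join(f"{k}={v!r}" for k, v in zip(schema.key_columns, key))
            report.add(
                ValidationError(
                    "duplicate_row",
                    name,
                    line,
                    "",
                    f"row repeats the key of line {seen[key]} ({keystr})",
                    "remove the duplicate row or correct its identifying columns",
                )
            )
        else:
            seen[key] = line
    return report


# ---------------------------------------------------------------------------
# DOIs
# ---------------------------------------------------------------------------


def check_doi(
    table: MetadataTable,
    online: bool = False,
    table_name: str | None = None,
    timeout: float = 10.0,
) -> ValidationReport:
    """Check publication DOIs.

    Offline (default, fully deterministic): syntax only, against
    :data:`DOI_PATTERN`.  Online: additionally require https://doi.org/<doi>
    to resolve; network failures are reported as warnings, never as
    ``invalid_doi``.
    """
    name = table_name or _table_name(table, None)
    idx = table.column_index("publication_doi")
    col_pos = idx + 1
    report = ValidationReport()
    for i, row in enumerate(table.rows):
        line = i + 2
        doi = row[idx]
        if doi == "" or doi == MISSING_TOKEN:
            continue  # emptiness/missing-token policy is the schema check's job
        if not DOI_PATTERN.match(doi):
            report.add(
                ValidationError(
                    "invalid_doi",
                    name,
                    line,
                    "publication_doi",
                    f"'{doi}' is not a syntactically valid DOI",
                    "use the form 10.<registrant>/<suffix> without a 'doi:' prefix",
                    col_pos=col_pos,
                )
            )
            continue
        if online:
            try:
                req = urllib.request.Request(
                    f"https://doi.org/{doi}", method="HEAD"
                )
                with urllib.request.urlopen(req, timeout=timeout) as resp:
                    ok = 200 <= resp.status < 400
            except urllib.error.HTTPError as exc:
                ok = 200 <= exc.code < 400
            except (urllib.error.URLError, OSError, TimeoutError) as exc:
                report.warnings.append(
                    f"{name} line {line}: could not resolve DOI '{doi}' ({exc}); "
                    "treating as unverified"
                )
                continue
            if not ok:
                report.add(
                    ValidationError(
                        "invalid_doi",
                        name,
                        line,
                        "publication_doi",
                        f"DOI '{doi}' does not resolve at doi.org",
                        "verify the DOI against the publisher's landing page",
                        col_pos=col_pos,
                    )
                )
    return report


# ---------------------------------------------------------------------------
# Accessions
# ---------------------------------------------------------------------------


def library_sample_key(
    library_row: list[str],
    lib_table: MetadataTable,
) -> tuple[str, list[str]]:
    """Return the linkage rule inputs for one library row.

    Libraries link to samples by archive sample accession when the column is
    present, else by exact sample-name match.
    """
    if "archive_sample_accession" in lib_table.header:
        idx = lib_table.column_index("archive_sample_accession")
        return "accession", _split_list(library_row[idx])
    idx = lib_table.column_index("sample_name")
    return "name", [library_row[idx]]


def _pattern_errors(
    table: MetadataTable,
    name: str,
    column: str,
    pattern: re.Pattern,
    what: str,
    report: ValidationReport,
) -> set[tuple[int, str]]:
    """Flag tokens failing ``pattern``; return {(line, token)} of bad cells."""
    bad: set[tuple[int, str]] = set()
    if column not in table.header:
        return bad
    idx = table.column_index(column)
    for i, row in enumerate(table.rows):
        line = i + 2
        cell = row[idx]
        if cell in ("", MISSING_TOKEN):
            continue
        for token in _split_list(cell):
            if not pattern.match(token):
                report.add(
                    ValidationError(
                        "invalid_accession",
                        name,
                        line,
                        column,
                        f"'{token}' is not a valid {what} accession",
                        f"check the {what} accession against the sequencing archive record",
                        col_pos=idx + 1,
                    )
                )
                bad.add((line, token))
                break  # one error per cell
    return bad


def check_accessions(
    samples: MetadataTable, libraries: MetadataTable
) -> ValidationReport:
    """Accession validity, uniqueness, and sample/project association.

    Emits ``invalid_accession`` for tokens outside the INSDC namespaces,
    ``duplicate_accession`` for a run accession on more than one library row,
    ``accession_project_mismatch`` when a library's project differs from its
    sample row's project, and ``orphan_library`` for library rows matching no
    sample.  A cell already flagged as invalid is excluded from the
    relationship checks so one defect yields one error.
    """
    s_schema, l_schema = samples.schema, libraries.schema
    if s_schema is None or l_schema is None:
        raise UsageError("check_accessions requires schema-bound tables")
    if s_schema.dataset_kind != l_schema.dataset_kind:
        raise UsageError(
            "samples and libraries tables belong to different dataset kinds"
        )
    report = ValidationReport()

    bad_s_proj = _pattern_errors(
        samples, "samples", "archive_project", PROJECT_ACCESSION_PATTERN, "project", report
    )
    _pattern_errors(
        samples, "samples", "archive_accession", BIOSAMPLE_ACCESSION_PATTERN, "sample", report
    )
    bad_l_proj = _pattern_errors(
        libraries, "libraries", "archive_project", PROJECT_ACCESSION_PATTERN, "project", report
    )
    bad_l_samp = _pattern_errors(
        libraries,
        "libraries",
        "archive_sample_accession",
        BIOSAMPLE_ACCESSION_PATTERN,
        "sample",
        report,
    )
    bad_l_run = _pattern_errors(
        libraries, "libraries", "archive_data_accession", RUN_ACCESSION_PATTERN, "run", report
    )

    # run-accession uniqueness across library rows
    run_idx = libraries.column_index("archive_data_accession")
    seen_runs: dict[str, int] = {}
    for i, row in enumerate(libraries.rows):
        line = i + 2
        for token in _split_list(row[run_idx]):
            if (line, token) in bad_l_run or not token:
                continue
            if token in seen_runs:
                report.add(
                    ValidationError(
                        "duplicate_accession",
                        "libraries",
                        line,
                        "archive_data_accession",
                        f"run accession '{token}' already appears on line {seen_runs[token]}",
                        "each sequencing run may be listed on exactly one library row",
                        col_pos=run_idx + 1,
                    )
                )
            else:
                seen_runs[token] = line

    # sample linkage: accession first, then exact sample-name match
    by_accession: dict[str, int] = {}
    by_name: dict[str, int] = {}
    s_acc_idx = (
        samples.column_index("archive_accession")
        if "archive_accession" in samples.header
        else None
    )
    s_name_idx = samples.column_index("sample_name")
    s_proj_idx = samples.column_index("archive_project")
    for i, row in enumerate(samples.rows):
        if s_acc_idx is not None:
            for token in _split_list(row[s_acc_idx]):
                by_accession.setdefault(token, i)
        by_name.setdefault(row[s_name_idx], i)

    l_proj_idx = libraries.column_index("archive_project")
    l_sampacc_idx = (
        libraries.column_index("archive_sample_accession")
        if "archive_sample_accession" in libraries.header
        else None
    )
    for i, row in enumerate(libraries.rows):
        line = i + 2
        mode, keys = library_sample_key(row, libraries)
        if mode == "accession" and any((line, t) in bad_l_samp for t in keys):
            continue  # already reported as invalid
        sample_i = None
        for key in keys:
            lookup = by_accession if mode == "accession" else by_name
            if key in lookup:
                sample_i = lookup[key]
                break
        if sample_i is None:
            keystr = LIST_SEPARATOR.join(keys)
            report.add(
                ValidationError(
                    "orphan_library",
                    "libraries",
                    line,
                    "archive_sample_accession" if mode == "accession" else "sample_name",
                    f"no sample row matches this library's sample {mode} '{keystr}'",
                    "add the sample row, or correct the library's sample reference",
                    col_pos=(l_sampacc_idx if mode == "accession" else libraries.column_index("sample_name")) + 1,
                )
            )
            continue
        lib_proj = row[l_proj_idx]
        samp_proj = samples.rows[sample_i][s_proj_idx]
        if (line, lib_proj) in bad_l_proj or (sample_i + 2, samp_proj) in bad_s_proj:
            continue
        if not set(_split_list(lib_proj)) & set(_split_list(samp_proj)):
            report.add(
                ValidationError(
                    "accession_project_mismatch",
                    "libraries",
                    line,
                    "archive_project",
                    f"library project '{lib_proj}' does not match its sample's project '{samp_proj}'",
                    "use the project accession under which the sample's runs were deposited",
                    col_pos=l_proj_idx + 1,
                )
            )
    return report.sorted()


# ---------------------------------------------------------------------------
# Whole-dataset validation
# ---------------------------------------------------------------------------


def validate_dataset(
    samples: MetadataTable,
    libraries: MetadataTable,
    schemas: tuple[TableSchema, TableSchema] | None = None,
    online_doi: bool = False,
) -> ValidationReport:
    """Run the full check battery over a samples/libraries table pair.

    Concatenates, in canonical order: per-cell schema validation of both
    tables, duplicate-row checks on both, DOI checks on samples, and the
    cross-table accession checks.  ``passed`` iff every sub-report passed.
    """
    if schemas is not None:
        samples = samples.bind(schemas[0])
        libraries = libraries.bind(schemas[1])
    if samples.schema is None or libraries.schema is None:
        raise UsageError("validate_dataset requires schema-bound tables (or schemas=)")
    report = ValidationReport()
    report.extend(validate_schema(samples))
    report.extend(validate_schema(libraries))
    report.extend(check_duplicates(samples))
    report.extend(check_duplicates(libraries))
    report.extend(check_doi(samples, online=online_doi, table_name="samples"))
    report.extend(check_accessions(samples, libraries))
    return report.sorted()


def validate_dataset_files(
    samples_path,
    libraries_path,
    schemas: tuple[TableSchema, TableSchema],
    online_doi: bool = False,
) -> ValidationReport:
    """File-level entry point: structural parse failures short-circuit into a
    single ``structural`` error instead of raising."""
    from .schema_model import read_table_file  # local import to avoid cycle noise

    tables = []
    for path, schema, label in (
        (samples_path, schemas[0], "samples"),
        (libraries_path, schemas[1], "libraries"),
    ):
        try:
            tables.append(read_table_file(path, schema=schema))
        except TableParseError as exc:
            return ValidationReport(
                [
                    ValidationError(
                        "structural",
                        label,
                        exc.line or 1,
                        "",
                        f"table could not be parsed: {exc}",
                        "fix the file structure so every row has one cell per header column",
                    )
                ]
            )
        except Exception as exc:  # header/schema binding failures
            return ValidationReport(
                [
                    ValidationError(
                        "header_mismatch",
                        label,
                        1,
                        "",
                        f"table header does not match its schema: {exc}",
                        "restore the canonical column names and order for this table type",
                    )
                ]
            )
    return validate_dataset(tables[0], tables[1], online_doi=online_doi)
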