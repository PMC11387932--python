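"""ENA read_run metadata client and library-table draft mapping.

The European Nucleotide Archive's portal API exposes a ``filereport``
endpoint that, for a project or sample accession, returns one row per
sequencing run with file locations, sizes and checksums alongside library
and instrument metadata.  ``autofill`` turns those rows into a draft
library table in the directory dialect; the ancient-DNA-specific columns
the archive cannot know (library construction method, indexing polymerase,
damage pretreatment) are filled with the missing-data token and reported
back so a submitter knows exactly what is left to curate by hand.

Network access is isolated behind :class:`Transport`: ``recorded`` mode
replays byte-for-byte fixture files from a directory and never opens a
connection, which is what every test uses; ``live`` mode performs HTTPS
GETs with bounded retries.
"""

from __future__ import annotations

import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import TableParseError, TransportError, UsageError
from .schema_model import (
    LIST_SEPARATOR,
    MISSING_TOKEN,
    DatasetKind,
    MetadataTable,
    builtin_schema,
)
from .validation import _MD5_RE

#: Fields requested from the ENA portal API, in response-column order.
#: Configuration, not contract: archives add fields over time.
ENA_FIELDS = (
    "study_accession",
    "sample_accession",
    "run_accession",
    "library_name",
    "instrument_model",
    "library_layout",
    "library_strategy",
    "read_count",
    "fastq_ftp",
    "fastq_md5",
    "fastq_bytes",
)

DEFAULT_ENDPOINT = "https://www.ebi.ac.uk/ena/portal/api/filereport"

#: aDNA-specific library columns the archive cannot populate.
ADNA_COLUMNS = ("strand_type", "library_polymerase", "library_treatment")


@dataclass(frozen=True)
class RunRecord:
    """One row of an ENA read_run report."""

    study_accession: str
    sample_accession: str
    run_accession: str
    library_name: str
    instrument_model: str
    library_layout: str  # SINGLE | PAIRED
    library_strategy: str
    read_count: int
    fastq_urls: tuple[str, ...]
    fastq_md5: tuple[str, ...]
    fastq_bytes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.fastq_urls) == len(self.fastq_md5) == len(self.fastq_bytes)):
            raise TableParseError(
                f"run {self.run_accession}: fastq url/md5/bytes lists have unequal lengths"
            )
        for md5 in self.fastq_md5:
            if not _MD5_RE.match(md5):
                raise TableParseError(
                    f"run {self.run_accession}: '{md5}' is not an md5 checksum"
                )
        if self.read_count < 0:
            raise TableParseError(
                f"run {self.run_accession}: negative read count"
            )


@dataclass(frozen=True)
class Transport:
    """How run reports are obtained.

    ``recorded`` replays ``<fixture_store>/<accession>.tsv`` files and never
    touches the network; ``live`` queries the portal endpoint with up to 3
    attempts and exponential backoff on 5xx responses.
    """

    mode: str = "recorded"  # "live" | "recorded"
    fixture_store: Path | None = None
    endpoint: str = DEFAULT_ENDPOINT
    timeout: float = 30.0
    max_attempts: int = 3
    backoff_base: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("live", "recorded"):
            raise UsageError(f"transport mode must be 'live' or 'recorded', got {self.mode!r}")
        if self.mode == "recorded" and self.fixture_store is None:
            raise UsageError("recorded transport requires a fixture_store directory")

    def get(self, accession: str) -> str:
        if self.mode == "recorded":
            path = Path(self.fixture_store) / f"{accession}.tsv"
            if not path.exists():
                raise TransportError(
                    f"no recorded response for {accession} under {self.fixture_store}",
                    status=404,
                )
            return path.read_text(encoding="utf-8")
        return self._get_live(accession)

    def _get_live(self, accession: str) -> str:
        query = urllib.parse.urlencode(
            {
                "accession": accession,
                "result": "read_run",
                "fields": ",".join(ENA_FIELDS),
                "format": "tsv",
            }
        )
        url = f"{self.endpoint}?{query}"
        last_exc: Exception | None = None
        for attempt in range(self.max_attempts):
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return resp.read().decode("utf-8")
            except urllib.error.HTTPError as exc:
                if 500 <= exc.code < 600 and attempt < self.max_attempts - 1:
                    time.sleep(self.backoff_base * 2**attempt)
                    last_exc = exc
                    continue
                raise TransportError(
                    f"ENA query for {accession} failed with HTTP {exc.code}",
                    status=exc.code,
                ) from exc
            except (urllib.error.URLError, OSError, TimeoutError) as exc:
                raise TransportError(
                    f"ENA query for {accession} failed: {exc}"
                ) from exc
        raise TransportError(f"ENA query for {accession} failed after retries") from last_exc


def _parse_report_row(fields: dict[str, str], rowno: int) -> RunRecord:
    def split(name: str) -> list[str]:
        cell = fields.get(name, "")
        return [t for t in cell.split(LIST_SEPARATOR)] if cell else []

    try:
        read_count = int(fields.get("read_count") or 0)
        sizes = tuple(int(t) for t in split("fastq_bytes"))
    except ValueError as exc:
        raise TableParseError(f"report row {rowno}: non-numeric field: {exc}") from exc
    return RunRecord(
        study_accession=fields.get("study_accession", ""),
        sample_accession=fields.get("sample_accession", ""),
        run_accession=fields.get("run_accession", ""),
        library_name=fields.get("library_name", ""),
        instrument_model=fields.get("instrument_model", ""),
        library_layout=fields.get("library_layout", ""),
        library_strategy=fields.get("library_strategy", ""),
        read_count=read_count,
        fastq_urls=tuple(split("fastq_ftp")),
        fastq_md5=tuple(split("fastq_md5")),
        fastq_bytes=sizes,
    )


def fetch_run_report(accession: str, transport: Transport) -> list[RunRecord]:
    """Fetch and parse the read_run report for one project/sample accession.

    Returns one :class:`RunRecord` per report row; an empty report is an
    empty list, not an error.  Multi-file fields are split on the archive's
    semicolon separator into parallel lists.
    """
    text = transport.get(accession)
    if not text.strip():
        return []
    lines = [ln for ln in text.split("\n") if ln != ""]
    header = lines[0].split("\t")
    records = []
    for rowno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise TableParseError(
                f"report row {rowno} for {accession}: {len(cells)} fields, "
                f"expected {len(header)}",
                line=rowno,
            )
        records.append(_parse_report_row(dict(zip(header, cells)), rowno))
    return records


def map_run_to_library_draft(
    records: Sequence[RunRecord], kind: DatasetKind
) -> tuple[MetadataTable, list[str]]:
    """Map run records onto a draft library table for ``kind``.

    Archive-derivable columns are populated; everything the archive cannot
    know is set to the missing-data token and named in the returned
    ``unfilled`` list, in schema order.  Row order follows record order.
    """
    if not records:
        raise UsageError("map_run_to_library_draft requires at least one record")
    schema = builtin_schema(kind, "libraries")
    unfilled = [
        c
        for c in schema.column_names
        if c
        in (
            "project_name",
            "publication_year",
            "publication_doi",
            "sample_name",
            *ADNA_COLUMNS,
        )
    ]
    rows = []
    for rec in records:
        cells = {
            "project_name": MISSING_TOKEN,
            "publication_year": MISSING_TOKEN,
            "publication_doi": MISSING_TOKEN,
            "sample_name": MISSING_TOKEN,
            "archive": "ENA",
            "archive_project": rec.study_accession,
            "archive_sample_accession": rec.sample_accession,
            "library_name": rec.library_name or MISSING_TOKEN,
            "strand_type": MISSING_TOKEN,
            "library_polymerase": MISSING_TOKEN,
            "library_treatment": MISSING_TOKEN,
            "instrument_model": rec.instrument_model or MISSING_TOKEN,
            "library_layout": rec.library_layout,
            "library_strategy": rec.library_strategy or MISSING_TOKEN,
            "read_count": str(rec.read_count),
            "archive_data_accession": rec.run_accession,
            "download_links": LIST_SEPARATOR.join(rec.fastq_urls),
            "download_md5s": LIST_SEPARATOR.join(rec.fastq_md5),
            "download_sizes": LIST_SEPARATOR.join(str(b) for b in rec.fastq_bytes),
        }
        rows.append([cells[name] for name in schema.column_names])
    draft = MetadataTable(
        list(schema.column_names), rows, provenance="ena-autofill", schema=schema
    )
    return draft, unfilled


def autofill(
    accessions: Sequence[str],
    kind: DatasetKind,
    transport: Transport,
) -> tuple[MetadataTable, list[str]]:
    """Fetch, map and concatenate drafts for several accessions.

    Rows are de-duplicated on run accession; order is input accession order,
    then archive row order.  A failing accession aborts with a transport
    error naming it.
    """
    if not accessions:
        raise UsageError("autofill requires at least one accession")
    all_records: list[RunRecord] = []
    seen_runs: set[str] = set()
    for accession in accessions:
        try:
            records = fetch_run_report(accession, transport)
        except TransportError as exc:
            raise TransportError(
                f"autofill failed for accession {accession}: {exc}",
                status=exc.status,
            ) from exc
        for rec in records:
            if rec.run_accession in seen_runs:
                continue
            seen_runs.add(rec.run_accession)
            all_records.append(rec)
    if not all_records:
        schema = builtin_schema(kind, "libraries")
        return (
            MetadataTable(list(schema.column_names), [], provenance="ena-autofill", schema=schema),
            [],
        )
    return map_run_to_library_draft(all_records, kind)
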