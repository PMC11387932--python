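"""Converters: download scripts, pipeline input sheets, citations, merging.

Everything here is deterministic text generation: identical inputs produce
byte-identical outputs, so generated artefacts can be diffed and checked
into version control alongside the metadata they came from.

The nf-core/eager sheet deserves a caveat its header comment repeats: it is
a *template*.  Archive metadata is heterogeneous and sometimes wrong, so
the sheet must be reviewed before running a pipeline on it.  Mapping
choices for uncertain ancient-DNA metadata are conservative: an unknown
damage pretreatment maps to ``none`` (so no damage trimming is silently
applied to an untreated library) and an unknown strand type maps to
``double`` (the overwhelmingly more common construction), each with a
logged warning.
"""

from __future__ import annotations

import logging
import re
import urllib.error
import urllib.request
from dataclasses import dataclass
from pathlib import Path

from .errors import ConversionError, MergeError, UsageError
from .query import join_libraries
from .schema_model import (
    LIST_SEPARATOR,
    MISSING_TOKEN,
    MetadataTable,
    TableSchema,
    write_table,
)
from .validation import check_duplicates, library_sample_key, validate_schema

logger = logging.getLogger("amdir.convert")

#: Canonical artefact file names.
DOWNLOAD_SCRIPT_NAME = "AncientMetagenomeDir_{tool}_download_script.sh"
EAGER_SHEET_NAME = "AncientMetagenomeDir_nf_core_eager_input_table.tsv"
BIBLIOGRAPHY_NAME = "AncientMetagenomeDir_bibliography.bib"
FILTERED_LIBRARIES_NAME = "AncientMetagenomeDir_filtered_libraries.tsv"

#: Substring → colour chemistry (2- vs 4-dye base calling).  Two-colour
#: platforms emit spurious poly-G tails on short ancient-DNA inserts, so
#: downstream trimming depends on this.  User-extendable via the
#: ``instrument_chemistry`` argument of :func:`make_eager_sheet`.
DEFAULT_INSTRUMENT_CHEMISTRY: tuple[tuple[str, int], ...] = (
    ("NextSeq", 2),
    ("NovaSeq", 2),
    ("HiSeq", 4),
    ("MiSeq", 4),
    ("Genome Analyzer", 4),
)

EAGER_COLUMNS = (
    "Sample_Name",
    "Library_ID",
    "Lane",
    "Colour_Chemistry",
    "SeqType",
    "Organism",
    "Strandedness",
    "UDG_Treatment",
    "R1",
    "R2",
    "BAM",
)


# ---------------------------------------------------------------------------
# Download scripts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DownloadScript:
    """A POSIX shell download script plus its file manifest."""

    tool: str  # "curl" | "wget"
    lines: tuple[str, ...]  # fetch commands, one per file
    manifest: tuple[tuple[str, str, str, int], ...]  # (filename, url, md5, bytes)

    @property
    def total_bytes(self) -> int:
        return sum(entry[3] for entry in self.manifest)

    def text(self) -> str:
        out = [
            "#!/usr/bin/env bash",
            "set -euo pipefail",
            "",
            f"# {len(self.manifest)} file(s) selected from library metadata",
        ]
        out.extend(self.lines)
        out.append("")
        out.append("md5sum -c <<'MD5SUMS'")
        for filename, _url, md5, _size in self.manifest:
            out.append(f"{md5}  {filename}")
        out.append("MD5SUMS")
        return "\n".join(out) + "\n"


def _row_files(row: list[str], table: MetadataTable, line: int):
    urls = row[table.column_index("download_links")]
    md5s = row[table.column_index("download_md5s")]
    sizes = row[table.column_index("download_sizes")]
    if not urls:
        return []
    url_list = urls.split(LIST_SEPARATOR)
    md5_list = md5s.split(LIST_SEPARATOR)
    size_list = sizes.split(LIST_SEPARATOR)
    if not (len(url_list) == len(md5_list) == len(size_list)):
        raise ConversionError(
            f"line {line}: download_links/download_md5s/download_sizes have "
            f"{len(url_list)}/{len(md5_list)}/{len(size_list)} entries; they must be parallel"
        )
    files = []
    for url, md5, size in zip(url_list, md5_list, size_list):
        try:
            nbytes = int(size)
        except ValueError:
            raise ConversionError(
                f"line {line}: download size {size!r} is not an integer"
            ) from None
        files.append((url.rsplit("/", 1)[-1], url, md5, nbytes))
    return files


def make_download_script(libraries: MetadataTable, tool: str = "curl") -> DownloadScript:
    """One fetch command per FASTQ file, ordered by row then list position,
    followed by an md5 verification block covering every file once."""
    if tool not in ("curl", "wget"):
        raise UsageError(f"download tool must be 'curl' or 'wget', got {tool!r}")
    lines: list[str] = []
    manifest: list[tuple[str, str, str, int]] = []
    for i, row in enumerate(libraries.rows):
        for filename, url, md5, nbytes in _row_files(row, libraries, i + 2):
            if tool == "curl":
                lines.append(f"curl -L -o '{filename}' '{url}'")
            else:
                lines.append(f"wget -O '{filename}' '{url}'")
            manifest.append((filename, url, md5, nbytes))
    return DownloadScript(tool, tuple(lines), tuple(manifest))


# ---------------------------------------------------------------------------
# nf-core/eager input sheet
# ---------------------------------------------------------------------------


def _chemistry_for(model: str, lookup: tuple[tuple[str, int], ...]) -> int | None:
    for substring, chemistry in lookup:
        if substring in model:
            return chemistry
    return None


def make_eager_sheet(
    samples: MetadataTable,
    libraries: MetadataTable,
    instrument_chemistry: tuple[tuple[str, int], ...] | None = None,
    local_filenames: bool = False,
) -> str:
    """Build an nf-core/eager (2.x) input TSV from a sample/library pair.

    One row per library; lanes are numbered sequentially per sample in
    library order (archives do not expose lane structure).  PAIRED layouts
    become SeqType PE with R1/R2 from the first two FASTQ entries; SINGLE
    becomes SE with R2 = NA.  R1/R2 reference the archive URLs verbatim so
    the sheet pairs with the download script's basenames unless
    ``local_filenames`` is set.
    """
    lookup = tuple(instrument_chemistry or ()) + DEFAULT_INSTRUMENT_CHEMISTRY
    acc_to_sample: dict[str, int] = {}
    name_to_sample: dict[str, int] = {}
    if "archive_accession" in samples.header:
        idx = samples.column_index("archive_accession")
        for i, row in enumerate(samples.rows):
            for token in row[idx].split(LIST_SEPARATOR):
                acc_to_sample.setdefault(token, i)
    sname_idx = samples.column_index("sample_name")
    for i, row in enumerate(samples.rows):
        name_to_sample.setdefault(row[sname_idx], i)
    host_idx = (
        samples.column_index("sample_host") if "sample_host" in samples.header else None
    )

    out_rows = []
    lanes_per_sample: dict[str, int] = {}
    for i, row in enumerate(libraries.rows):
        line = i + 2
        mode, keys = library_sample_key(row, libraries)
        sample_i = None
        for key in keys:
            pool = acc_to_sample if mode == "accession" else name_to_sample
            if key in pool:
                sample_i = pool[key]
                break
        if sample_i is None:
            raise ConversionError(
                f"line {line}: library matches no sample row; join the tables before converting"
            )
        sample_row = samples.rows[sample_i]
        sample_name = sample_row[sname_idx]
        library_id = row[libraries.column_index("library_name")]

        model = row[libraries.column_index("instrument_model")]
        chemistry = _chemistry_for(model, lookup)
        if chemistry is None:
            raise ConversionError(
                f"line {line}: instrument model {model!r} is not in the colour-"
                "chemistry lookup; extend it via instrument_chemistry="
                "((substring, 2_or_4), ...)"
            )

        layout = row[libraries.column_index("library_layout")]
        urls = [
            u
            for u in row[libraries.column_index("download_links")].split(LIST_SEPARATOR)
            if u
        ]
        if not urls:
            raise ConversionError(f"line {line}: library has no FASTQ URLs")
        if layout == "PAIRED":
            if len(urls) < 2:
                raise ConversionError(
                    f"line {line}: PAIRED layout but only {len(urls)} FASTQ URL(s)"
                )
            seq_type, r1, r2 = "PE", urls[0], urls[1]
        elif layout == "SINGLE":
            seq_type, r1, r2 = "SE", urls[0], "NA"
        else:
            raise ConversionError(
                f"line {line}: library layout {layout!r} is neither SINGLE nor PAIRED"
            )
        if local_filenames:
            r1 = r1.rsplit("/", 1)[-1]
            r2 = r2 if r2 == "NA" else r2.rsplit("/", 1)[-1]

        strand = row[libraries.column_index("strand_type")]
        if strand == MISSING_TOKEN:
            logger.warning(
                "line %d: strand type unknown; assuming double-stranded in eager sheet",
                line,
            )
            strand = "double"
        if strand not in ("double", "single"):
            raise ConversionError(
                f"line {line}: strand type {strand!r} is neither double nor single"
            )

        udg = row[libraries.column_index("library_treatment")]
        if udg == MISSING_TOKEN:
            logger.warning(
                "line %d: UDG treatment unknown; assuming 'none' in eager sheet "
                "(avoids inappropriate damage trimming)",
                line,
            )
            udg = "none"
        if udg not in ("none", "half", "full"):
            raise ConversionError(
                f"line {line}: UDG treatment {udg!r} is not one of none/half/full"
            )

        organism = "NA"
        if host_idx is not None:
            host = sample_row[host_idx]
            if host and host != MISSING_TOKEN:
                organism = host

        lane = lanes_per_sample.get(sample_name, 0) + 1
        lanes_per_sample[sample_name] = lane

        out_rows.append(
            [
                sample_name,
                library_id,
                str(lane),
                str(chemistry),
                seq_type,
                organism,
                strand,
                udg,
                r1,
                r2,
                "NA",
            ]
        )
    lines = ["\t".join(EAGER_COLUMNS)]
    lines.extend("\t".join(r) for r in out_rows)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Bibliography
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BibEntry:
    key: str
    doi: str
    entry_type: str = "misc"
    fields: tuple[tuple[str, str], ...] = ()

    def render(self) -> str:
        body = [f"@{self.entry_type}{{{self.key},"]
        all_fields = (("doi", self.doi),) + self.fields
        body.extend(f"  {name} = {{{value}}}," for name, value in all_fields)
        body[-1] = body[-1].rstrip(",")
        body.append("}")
        return "\n".join(body)


def _bib_key(doi: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", doi)


def make_bibliography(
    samples_subset: MetadataTable, mode: str = "offline", timeout: float = 10.0
) -> str:
    """One BibTeX entry per distinct publication DOI, sorted by key.

    Offline (default): minimal entries with doi and url fields.  Online:
    fields are filled via DOI content negotiation; a failed resolution
    degrades to the offline entry with a logged warning.
    """
    if mode not in ("offline", "online"):
        raise UsageError(f"bibliography mode must be 'offline' or 'online', got {mode!r}")
    doi_idx = samples_subset.column_index("publication_doi")
    dois: list[str] = []
    for row in samples_subset.rows:
        doi = row[doi_idx]
        if doi and doi != MISSING_TOKEN and doi not in dois:
            dois.append(doi)
    entries: list[BibEntry | str] = []
    used_keys: set[str] = set()
    for doi in dois:
        key = _bib_key(doi)
        while key in used_keys:
            key += "_"
        used_keys.add(key)
        if mode == "online":
            try:
                req = urllib.request.Request(
                    f"https://doi.org/{doi}",
                    headers={"Accept": "application/x-bibtex"},
                )
                with urllib.request.urlopen(req, timeout=timeout) as resp:
                    entries.append((key, resp.read().decode("utf-8").strip()))
                    continue
            except (urllib.error.URLError, OSError, TimeoutError) as exc:
                logger.warning(
                    "could not resolve DOI %s online (%s); writing minimal entry",
                    doi,
                    exc,
                )
        entries.append(
            (
                key,
                BibEntry(
                    key,
                    doi,
                    fields=(("url", f"https://doi.org/{doi}"),),
                ).render(),
            )
        )
    entries.sort(key=lambda pair: pair[0])
    return "\n\n".join(text for _key, text in entries) + ("\n" if entries else "")


# ---------------------------------------------------------------------------
# Export orchestration
# ---------------------------------------------------------------------------


def export_tables(
    samples: MetadataTable,
    libraries: MetadataTable,
    outdir: str | Path,
    curl: bool = False,
    wget: bool = False,
    eager: bool = False,
    bibliography: bool = False,
    librarymetadata: bool = False,
    bibliography_mode: str = "offline",
) -> list[Path]:
    """Write the requested artefacts under their canonical file names.

    Returns the written paths.  Re-running on identical inputs rewrites
    byte-identical files.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise UsageError(f"cannot create output directory {outdir}: {exc}") from exc
    written: list[Path] = []

    def emit(name: str, text: str) -> None:
        path = outdir / name
        try:
            path.write_text(text, encoding="utf-8", newline="")
        except OSError as exc:
            raise UsageError(f"cannot write {path}: {exc}") from exc
        written.append(path)

    if librarymetadata:
        emit(FILTERED_LIBRARIES_NAME, write_table(libraries))
    if curl:
        emit(
            DOWNLOAD_SCRIPT_NAME.format(tool="curl"),
            make_download_script(libraries, "curl").text(),
        )
    if wget:
        emit(
            DOWNLOAD_SCRIPT_NAME.format(tool="wget"),
            make_download_script(libraries, "wget").text(),
        )
    if eager:
        emit(EAGER_SHEET_NAME, make_eager_sheet(samples, libraries))
    if bibliography:
        emit(BIBLIOGRAPHY_NAME, make_bibliography(samples, mode=bibliography_mode))
    return written


def convert_selection(
    samples: MetadataTable,
    libraries: MetadataTable,
    outdir: str | Path,
    prefiltered_libraries: bool = False,
    **artefacts,
) -> list[Path]:
    """High-level convert: join libraries to the (filtered) samples unless the
    caller supplies an already-filtered libraries table, then export."""
    selected = libraries if prefiltered_libraries else join_libraries(samples, libraries)
    return export_tables(samples, selected, outdir, **artefacts)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def merge_tables(
    existing: MetadataTable,
    new: MetadataTable,
    schema: TableSchema | None = None,
) -> MetadataTable:
    """Append ``new`` rows after ``existing``, refusing key collisions.

    Both tables must share an identical header and be individually
    schema-valid; the merged result passes schema validation and the
    duplicate check by construction.
    """
    schema = schema or existing.schema or new.schema
    if schema is None:
        raise UsageError("merge_tables requires a schema (bound or explicit)")
    if list(existing.header) != list(new.header):
        raise MergeError(
            f"headers differ: {existing.header} vs {new.header}"
        )
    for label, table in (("existing", existing), ("new", new)):
        report = validate_schema(table, schema).extend(check_duplicates(table, schema))
        if not report.passed:
            first = report.errors[0]
            raise MergeError(
                f"{label} table is not valid before merging "
                f"({len(report.errors)} error(s); first: {first.message})"
            )
    key_idx = [existing.column_index(k) for k in schema.key_columns]
    existing_keys = {tuple(row[j] for j in key_idx) for row in existing.rows}
    collisions = []
    for row in new.rows:
        key = tuple(row[j] for j in key_idx)
        if key in existing_keys:
            collisions.append(key)
    if collisions:
        rendered = ", ".join(
            "(" + ", ".join(f"{k}={v!r}" for k, v in zip(schema.key_columns, key)) + ")"
            for key in collisions
        )
        raise MergeError(f"new rows duplicate existing keys: {rendered}")
    merged = MetadataTable(
        list(existing.header),
        [list(r) for r in existing.rows] + [list(r) for r in new.rows],
        provenance=existing.provenance or new.provenance,
        schema=schema,
    )
    return merged
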