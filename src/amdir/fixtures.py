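"""Seeded synthetic datasets and systematically corrupted variants.

The generator produces schema-valid sample/library table pairs for any of
the three dataset categories, together with matching per-project run
reports in the recorded-transport layout, from a single explicit random
seed (no global state; identical seed, identical bytes).

``corrupt_dataset`` then plants controlled defects mirroring the error
taxonomy real curation repeatedly encounters — mangled DOIs, out-of-
vocabulary cells, duplicated rows and run accessions, project mismatches,
and libraries uploaded under sample accessions that match no sample row —
and records every mutation in a manifest.  The manifest is the oracle for
the validator: validation of a corrupted bundle must report exactly the
manifest, no more, no less.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import CapacityError, UsageError
from .schema_model import (
    LIST_SEPARATOR,
    MISSING_TOKEN,
    DatasetKind,
    HOST_ASSOCIATED_METAGENOME,
    MetadataTable,
    builtin_schema,
    write_table_file,
)
from .ena import ENA_FIELDS

#: Error kinds that corrupt_dataset can plant: the row-scoped validation
#: error types (header/structural defects are table-level, not cell-level).
CORRUPTIBLE_KINDS = (
    "schema_violation",
    "enum_violation",
    "duplicate_row",
    "duplicate_accession",
    "invalid_doi",
    "invalid_accession",
    "accession_project_mismatch",
    "orphan_library",
)

_COUNTRIES = (
    "Germany",
    "United Kingdom",
    "Mexico",
    "Denmark",
    "Sweden",
    "Italy",
    "France",
    "Portugal",
)

_HOSTS = ("Homo sapiens", "Canis lupus familiaris", "Ursus arctos")
_SPECIES = ("Yersinia pestis", "Mycobacterium tuberculosis", "Helicobacter pylori")
_FEATURES = ("lake sediment core", "cave floor", "permafrost profile")
_MATERIALS = ("dental calculus", "tooth", "bone", "coprolite", "sediment")
_COMMUNITY_TYPES = ("oral", "gut", "skeletal tissue")
_INSTRUMENTS = (
    "Illumina HiSeq 2500",
    "Illumina HiSeq 4000",
    "Illumina MiSeq",
    "Illumina NovaSeq 6000",
    "NextSeq 500",
    "NextSeq 2000",
    "HiSeq X Ten",
    "Illumina Genome Analyzer II",
)
_STRATEGIES = ("WGS", "Target-Capture")


@dataclass
class FixtureBundle:
    """A generated dataset: tables plus matching run-report fixtures."""

    samples: MetadataTable
    libraries: MetadataTable
    run_report_fixtures: dict[str, str]
    seed: int
    kind: DatasetKind = HOST_ASSOCIATED_METAGENOME


@dataclass(frozen=True)
class CorruptionEntry:
    error_type: str
    table_name: str
    line: int
    column: str
    description: str

    @property
    def location(self) -> tuple[str, int, str]:
        return (self.table_name, self.line, self.column)


@dataclass
class CorruptionManifest:
    entries: list[CorruptionEntry] = field(default_factory=list)

    def locations(self) -> set[tuple[str, int, str, str]]:
        return {
            (e.table_name, e.line, e.column, e.error_type) for e in self.entries
        }


def _md5(rng: random.Random) -> str:
    return "".join(rng.choice("0123456789abcdef") for _ in range(32))


def generate_dataset(
    n_samples: int,
    libs_per_sample: int | tuple[int, int] = (1, 3),
    kind: DatasetKind = HOST_ASSOCIATED_METAGENOME,
    seed: int = 0,
    spain_fraction: float = 0.25,
    year_range: tuple[int, int] = (2015, 2024),
) -> FixtureBundle:
    """Generate a schema-valid bundle.

    ``libs_per_sample`` is either an exact count or an inclusive
    ``(low, high)`` range sampled per sample.  ``spain_fraction`` of samples
    carry geo_loc_name "Spain" and publication years span ``year_range``,
    so the published-since-2020-from-Spain walkthrough always has material
    to select.  Deterministic for a fixed argument set.
    """
    if n_samples < 1:
        raise UsageError("n_samples must be >= 1")
    if isinstance(libs_per_sample, int):
        if libs_per_sample < 1:
            raise UsageError("libs_per_sample must be >= 1")
        lib_range = (libs_per_sample, libs_per_sample)
    else:
        lib_range = tuple(libs_per_sample)  # type: ignore[assignment]
        if len(lib_range) != 2 or lib_range[0] < 1 or lib_range[1] < lib_range[0]:
            raise UsageError("libs_per_sample range must be (low, high) with 1 <= low <= high")
    if not 0.0 <= spain_fraction <= 1.0:
        raise UsageError("spain_fraction must be in [0, 1]")
    rng = random.Random(seed)

    samples_schema = builtin_schema(kind, "samples")
    libraries_schema = builtin_schema(kind, "libraries")

    # assign samples to projects in runs of 1-3
    projects: list[dict] = []
    assigned = 0
    while assigned < n_samples:
        size = min(rng.randint(1, 3), n_samples - assigned)
        p = len(projects) + 1
        projects.append(
            {
                "accession": f"PRJEB{40000 + p}",
                "name": f"FixtureProject{p}",
                "doi": f"10.99999/fixture.{p:03d}",
                "year": rng.randint(*year_range),
                "n": size,
            }
        )
        assigned += size

    sample_rows: list[list[str]] = []
    library_rows: list[list[str]] = []
    report_rows: dict[str, list[list[str]]] = {p["accession"]: [] for p in projects}
    sample_no = 0
    run_no = 0
    for p_idx, project in enumerate(projects):
        for _ in range(project["n"]):
            sample_no += 1
            sample_name = f"FIX{sample_no:04d}"
            biosample = f"SAMEA{7000000 + sample_no}"
            geo = "Spain" if rng.random() < spain_fraction else rng.choice(_COUNTRIES)
            cells = {
                "project_name": project["name"],
                "publication_year": str(project["year"]),
                "publication_doi": project["doi"],
                "site_name": f"Site_{p_idx + 1}_{sample_no}",
                "latitude": f"{rng.uniform(-89, 89):.4f}",
                "longitude": f"{rng.uniform(-179, 179):.4f}",
                "geo_loc_name": geo,
                "sample_name": sample_name,
                "sample_host": rng.choice(_HOSTS),
                "depth": f"{rng.uniform(0.1, 30.0):.2f}",
                "sample_age": str(rng.randint(150, 12000)),
                "sample_age_doi": MISSING_TOKEN,
                "community_type": rng.choice(_COMMUNITY_TYPES),
                "species": rng.choice(_SPECIES),
                "feature": rng.choice(_FEATURES),
                "material": rng.choice(_MATERIALS),
                "archive": "ENA",
                "archive_project": project["accession"],
                "archive_accession": biosample,
            }
            sample_rows.append([cells[c] for c in samples_schema.column_names])

            for lib_i in range(rng.randint(*lib_range)):
                run_no += 1
                run_acc = f"ERR{3000000 + run_no}"
                library_name = f"{sample_name}_L{lib_i + 1}"
                layout = "PAIRED" if rng.random() < 0.6 else "SINGLE"
                n_files = 2 if layout == "PAIRED" else 1
                base = f"https://ftp.fixture.invalid/vol1/run/{run_acc}/{run_acc}"
                if n_files == 2:
                    urls = [f"{base}_1.fastq.gz", f"{base}_2.fastq.gz"]
                else:
                    urls = [f"{base}.fastq.gz"]
                md5s = [_md5(rng) for _ in urls]
                sizes = [str(rng.randint(10**6, 10**9)) for _ in urls]
                strand = "single" if rng.random() < 0.15 else "double"
                treatment = rng.choice(("none", "none", "half", "full", MISSING_TOKEN))
                polymerase = rng.choice(
                    ("proofreading", "non-proofreading", MISSING_TOKEN)
                )
                instrument = rng.choice(_INSTRUMENTS)
                strategy = rng.choice(_STRATEGIES)
                read_count = str(rng.randint(10**5, 5 * 10**7))
                lib_cells = {
                    "project_name": project["name"],
                    "publication_year": str(project["year"]),
                    "publication_doi": project["doi"],
                    "sample_name": sample_name,
                    "archive": "ENA",
                    "archive_project": project["accession"],
                    "archive_sample_accession": biosample,
                    "library_name": library_name,
                    "strand_type": strand,
                    "library_polymerase": polymerase,
                    "library_treatment": treatment,
                    "instrument_model": instrument,
                    "library_layout": layout,
                    "library_strategy": strategy,
                    "read_count": read_count,
                    "archive_data_accession": run_acc,
                    "download_links": LIST_SEPARATOR.join(urls),
                    "download_md5s": LIST_SEPARATOR.join(md5s),
                    "download_sizes": LIST_SEPARATOR.join(sizes),
                }
                library_rows.append(
                    [lib_cells[c] for c in libraries_schema.column_names]
                )
                report_rows[project["accession"]].append(
                    [
                        project["accession"],
                        biosample,
                        run_acc,
                        library_name,
                        instrument,
                        layout,
                        strategy,
                        read_count,
                        LIST_SEPARATOR.join(urls),
                        LIST_SEPARATOR.join(md5s),
                        LIST_SEPARATOR.join(sizes),
                    ]
                )

    samples = MetadataTable(
        list(samples_schema.column_names),
        sample_rows,
        provenance=f"fixture:seed={seed}",
        schema=samples_schema,
    )
    libraries = MetadataTable(
        list(libraries_schema.column_names),
        library_rows,
        provenance=f"fixture:seed={seed}",
        schema=libraries_schema,
    )
    reports = {
        acc: "\n".join(
            ["\t".join(ENA_FIELDS)] + ["\t".join(r) for r in rows]
        )
        + "\n"
        for acc, rows in report_rows.items()
    }
    return FixtureBundle(samples, libraries, reports, seed, kind)


# ---------------------------------------------------------------------------
# Corruption
# ---------------------------------------------------------------------------


def _copy_table(table: MetadataTable) -> MetadataTable:
    return MetadataTable(
        list(table.header),
        [list(r) for r in table.rows],
        table.provenance,
        table.schema,
    )


class _Corruptor:
    """Bookkeeping for non-overlapping cell mutations."""

    def __init__(self, bundle: FixtureBundle, rng: random.Random):
        self.samples = _copy_table(bundle.samples)
        self.libraries = _copy_table(bundle.libraries)
        self.rng = rng
        self.touched: set[tuple[str, int, str]] = set()
        self.manifest = CorruptionManifest()

    def table(self, name: str) -> MetadataTable:
        return self.samples if name == "samples" else self.libraries

    def reserve(self, table: str, line: int, column: str) -> None:
        self.touched.add((table, line, column))

    def free_lines(self, table_name: str, columns: list[str], min_rows: int = 1):
        """Data lines where none of ``columns`` has been touched yet."""
        table = self.table(table_name)
        lines = [
            i + 2
            for i in range(len(table.rows))
            if all((table_name, i + 2, c) not in self.touched for c in columns)
        ]
        return lines

    def pick_line(self, table_name: str, columns: list[str], kind: str) -> int:
        lines = self.free_lines(table_name, columns)
        if not lines:
            raise CapacityError(
                f"bundle too small: no free {table_name} row left for a "
                f"{kind} corruption"
            )
        return self.rng.choice(lines)

    def set_cell(self, table_name: str, line: int, column: str, value: str) -> str:
        table = self.table(table_name)
        idx = table.column_index(column)
        old = table.rows[line - 2][idx]
        table.rows[line - 2][idx] = value
        self.reserve(table_name, line, column)
        return old

    def record(self, error_type: str, table_name: str, line: int, column: str, description: str) -> None:
        self.manifest.entries.append(
            CorruptionEntry(error_type, table_name, line, column, description)
        )


def _apply_corruption(c: _Corruptor, kind: str) -> None:
    rng = c.rng
    if kind == "schema_violation":
        line = c.pick_line("libraries", ["read_count"], kind)
        old = c.set_cell("libraries", line, "read_count", "many")
        c.record(kind, "libraries", line, "read_count", f"read_count {old!r} -> 'many'")
    elif kind == "enum_violation":
        line = c.pick_line("libraries", ["library_treatment"], kind)
        old = c.set_cell("libraries", line, "library_treatment", "halfish")
        c.record(
            kind, "libraries", line, "library_treatment", f"treatment {old!r} -> 'halfish'"
        )
    elif kind == "invalid_doi":
        line = c.pick_line("samples", ["publication_doi"], kind)
        old = c.set_cell("samples", line, "publication_doi", "doi:not-a-doi")
        c.record(
            kind, "samples", line, "publication_doi", f"DOI {old!r} -> 'doi:not-a-doi'"
        )
    elif kind == "duplicate_row":
        # copy an earlier row's key cell into a later row; key columns are
        # chosen so nothing else (linkage, accession checks) depends on them
        key_col = c.samples.schema.key_columns[0]
        lines = c.free_lines("samples", [key_col])
        if len(lines) < 2:
            raise CapacityError("bundle too small for a duplicate_row corruption")
        source, line = sorted(rng.sample(lines, 2))
        value = c.samples.rows[source - 2][c.samples.column_index(key_col)]
        c.set_cell("samples", line, key_col, value)
        c.reserve("samples", source, key_col)
        c.record(
            kind, "samples", line, "", f"{key_col} copied from line {source} ({value!r})"
        )
    elif kind == "duplicate_accession":
        lines = c.free_lines("libraries", ["archive_data_accession"])
        if len(lines) < 2:
            raise CapacityError("bundle too small for a duplicate_accession corruption")
        source, line = sorted(rng.sample(lines, 2))
        value = c.libraries.rows[source - 2][
            c.libraries.column_index("archive_data_accession")
        ]
        c.set_cell("libraries", line, "archive_data_accession", value)
        c.reserve("libraries", source, "archive_data_accession")
        c.record(
            kind,
            "libraries",
            line,
            "archive_data_accession",
            f"run accession copied from line {source} ({value!r})",
        )
    elif kind == "invalid_accession":
        line = c.pick_line("libraries", ["archive_data_accession"], kind)
        old = c.set_cell("libraries", line, "archive_data_accession", "XR123")
        c.record(
            kind,
            "libraries",
            line,
            "archive_data_accession",
            f"run accession {old!r} -> 'XR123'",
        )
    elif kind == "accession_project_mismatch":
        # fresh, valid-looking project accession disagreeing with the sample row
        line = c.pick_line(
            "libraries", ["archive_project", "archive_sample_accession"], kind
        )
        fresh = f"PRJEB{900000 + rng.randint(0, 9999)}"
        old = c.set_cell("libraries", line, "archive_project", fresh)
        c.reserve("libraries", line, "archive_sample_accession")
        c.record(
            kind, "libraries", line, "archive_project", f"project {old!r} -> {fresh!r}"
        )
    elif kind == "orphan_library":
        # the real-world upload error: a library deposited under its own
        # fresh sample accession that matches no sample row
        line = c.pick_line(
            "libraries", ["archive_sample_accession", "archive_project"], kind
        )
        fresh = f"SAMEA{9900000 + rng.randint(0, 9999)}"
        old = c.set_cell("libraries", line, "archive_sample_accession", fresh)
        c.reserve("libraries", line, "archive_project")
        c.record(
            kind,
            "libraries",
            line,
            "archive_sample_accession",
            f"sample accession {old!r} -> unique {fresh!r}",
        )
    else:
        raise UsageError(
            f"unknown corruption kind {kind!r}; known: {CORRUPTIBLE_KINDS}"
        )


def corrupt_dataset(
    bundle: FixtureBundle,
    error_kinds: tuple[str, ...] = CORRUPTIBLE_KINDS,
    k_per_kind: int = 1,
    seed: int = 0,
) -> tuple[FixtureBundle, CorruptionManifest]:
    """Plant ``k_per_kind`` corruptions of each requested kind.

    Corruptions land at distinct cells (a cell is never mutated twice) and
    are mutually non-interacting, so validation must report exactly the
    manifest.  Raises :class:`CapacityError` when the bundle cannot host the
    request.
    """
    if k_per_kind < 1:
        raise UsageError("k_per_kind must be >= 1")
    unknown = set(error_kinds) - set(CORRUPTIBLE_KINDS)
    if unknown:
        raise UsageError(f"cannot plant corruption kinds {sorted(unknown)}")
    rng = random.Random(seed)
    c = _Corruptor(bundle, rng)
    for kind in error_kinds:
        for _ in range(k_per_kind):
            _apply_corruption(c, kind)
    corrupted = FixtureBundle(
        c.samples, c.libraries, dict(bundle.run_report_fixtures), bundle.seed, bundle.kind
    )
    return corrupted, c.manifest


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------


def write_fixture_bundle(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write samples/libraries TSVs plus run reports in the recorded-transport
    layout (``ena/<accession>.tsv``); returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["samples"] = write_table_file(
        bundle.samples, outdir / f"{bundle.kind.dir_name}_samples.tsv"
    )
    paths["libraries"] = write_table_file(
        bundle.libraries, outdir / f"{bundle.kind.dir_name}_libraries.tsv"
    )
    ena_dir = outdir / "ena"
    ena_dir.mkdir(exist_ok=True)
    for accession, text in bundle.run_report_fixtures.items():
        p = ena_dir / f"{accession}.tsv"
        p.write_text(text, encoding="utf-8", newline="")
        paths[accession] = p
    return paths
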