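"""Download scripts, eager sheets, bibliographies, export and merge."""

import logging

import pytest

from amdir import (
    ConversionError,
    MergeError,
    MetadataTable,
    generate_dataset,
    join_libraries,
    make_bibliography,
    make_download_script,
    make_eager_sheet,
    merge_tables,
    parse_expression,
    filter_table,
    summarize_selection,
    export_tables,
)
from amdir.convert import (
    BIBLIOGRAPHY_NAME,
    DOWNLOAD_SCRIPT_NAME,
    EAGER_COLUMNS,
    EAGER_SHEET_NAME,
    FILTERED_LIBRARIES_NAME,
)


def _lib_row(libraries, line, **overrides):
    row = list(libraries.rows[line - 2])
    for col, value in overrides.items():
        row[libraries.column_index(col)] = value
    libraries.rows[line - 2] = row


class TestDownloadScript:
    def test_one_library_two_fastqs_gives_two_commands_and_manifest_lines(self):
        b = generate_dataset(1, 1, seed=3)
        _lib_row(
            b.libraries, 2,
            library_layout="PAIRED",
            download_links="https://x.invalid/a_1.fq.gz;https://x.invalid/a_2.fq.gz",
            download_md5s="a" * 32 + ";" + "b" * 32,
            download_sizes="10;20",
        )
        script = make_download_script(b.libraries, "curl")
        assert len(script.lines) == 2
        assert len(script.manifest) == 2
        text = script.text()
        assert text.count("curl -L -o") == 2
        assert "a_1.fq.gz" in text

    def test_empty_selection_script_has_header_but_no_fetches(self, libraries_schema):
        empty = MetadataTable(list(libraries_schema.column_names), [])
        script = make_download_script(empty, "wget")
        text = script.text()
        assert text.startswith("#!/usr/bin/env bash\nset -euo pipefail\n")
        assert "wget" not in text

    def test_command_count_equals_flat_url_count(self):
        b = generate_dataset(10, 1, seed=8)
        flat = sum(
            len(cell.split(";"))
            for cell in b.libraries.column("download_links")
        )
        script = make_download_script(b.libraries, "curl")
        assert len(script.lines) == flat

    def test_md5_url_length_mismatch_names_the_line(self, bundle):
        _lib_row(bundle.libraries, 4, download_md5s="0" * 32)
        _lib_row(bundle.libraries, 4, download_links="https://a.invalid/1;https://a.invalid/2")
        with pytest.raises(ConversionError, match="line 4"):
            make_download_script(bundle.libraries)

    def test_golden_script_template(self, libraries_schema):
        header = list(libraries_schema.column_names)
        cells = {c: "" for c in header}
        cells.update(
            download_links="https://ftp.x.invalid/ERR1/ERR1.fastq.gz",
            download_md5s="d" * 32,
            download_sizes="42",
            archive_data_accession="ERR3000001",
        )
        table = MetadataTable(header, [[cells[c] for c in header]])
        expected = (
            "#!/usr/bin/env bash\n"
            "set -euo pipefail\n"
            "\n"
            "# 1 file(s) selected from library metadata\n"
            "curl -L -o 'ERR1.fastq.gz' 'https://ftp.x.invalid/ERR1/ERR1.fastq.gz'\n"
            "\n"
            "md5sum -c <<'MD5SUMS'\n"
            f"{'d' * 32}  ERR1.fastq.gz\n"
            "MD5SUMS\n"
        )
        assert make_download_script(table, "curl").text() == expected

    def test_manifest_bytes_equal_selection_summary(self, bundle):
        script = make_download_script(bundle.libraries)
        assert script.total_bytes == summarize_selection(bundle.libraries).total_bytes


class TestEagerSheet:
    def test_half_udg_maps_to_half(self, bundle):
        _lib_row(bundle.libraries, 2, library_treatment="half")
        sheet = make_eager_sheet(bundle.samples, bundle.libraries)
        row = sheet.strip().split("\n")[1].split("\t")
        assert row[EAGER_COLUMNS.index("UDG_Treatment")] == "half"

    def test_single_layout_maps_to_se_with_na_r2(self, bundle):
        url = "https://ftp.x.invalid/ERR9/ERR9.fastq.gz"
        _lib_row(
            bundle.libraries, 2,
            library_layout="SINGLE", download_links=url,
            download_md5s="0" * 32, download_sizes="5",
        )
        sheet = make_eager_sheet(bundle.samples, bundle.libraries)
        row = sheet.strip().split("\n")[1].split("\t")
        assert row[EAGER_COLUMNS.index("SeqType")] == "SE"
        assert row[EAGER_COLUMNS.index("R1")] == url
        assert row[EAGER_COLUMNS.index("R2")] == "NA"

    @pytest.mark.parametrize(
        "model,chemistry",
        [("NextSeq 500", "2"), ("Illumina HiSeq 4000", "4"),
         ("Illumina NovaSeq 6000", "2"), ("Illumina MiSeq", "4")],
    )
    def test_instrument_to_colour_chemistry_lookup(self, bundle, model, chemistry):
        _lib_row(bundle.libraries, 2, instrument_model=model)
        sheet = make_eager_sheet(bundle.samples, bundle.libraries)
        row = sheet.strip().split("\n")[1].split("\t")
        assert row[EAGER_COLUMNS.index("Colour_Chemistry")] == chemistry

    def test_unknown_pretreatment_becomes_none_with_warning(self, bundle, caplog):
        _lib_row(bundle.libraries, 2, library_treatment="unknown")
        with caplog.at_level(logging.WARNING, logger="amdir.convert"):
            sheet = make_eager_sheet(bundle.samples, bundle.libraries)
        row = sheet.strip().split("\n")[1].split("\t")
        assert row[EAGER_COLUMNS.index("UDG_Treatment")] == "none"
        assert any("UDG" in rec.message for rec in caplog.records)

    def test_unlisted_instrument_errors_and_suggests_override(self, bundle):
        _lib_row(bundle.libraries, 2, instrument_model="unknown")
        with pytest.raises(ConversionError, match="instrument_chemistry"):
            make_eager_sheet(bundle.samples, bundle.libraries)
        # the override flag unblocks the conversion
        sheet = make_eager_sheet(
            bundle.samples, bundle.libraries, instrument_chemistry=(("unknown", 4),)
        )
        assert sheet

    def test_sheet_reparses_and_satisfies_row_invariants(self, bundle):
        sheet = make_eager_sheet(bundle.samples, bundle.libraries)
        lines = sheet.strip().split("\n")
        assert lines[0].split("\t") == list(EAGER_COLUMNS)
        assert len(lines) - 1 == len(bundle.libraries)
        lanes_seen = {}
        for line in lines[1:]:
            row = dict(zip(EAGER_COLUMNS, line.split("\t")))
            assert row["Colour_Chemistry"] in {"2", "4"}
            assert row["SeqType"] in {"SE", "PE"}
            assert (row["SeqType"] == "PE") == (row["R2"] != "NA")
            assert row["Strandedness"] in {"double", "single"}
            assert row["UDG_Treatment"] in {"none", "half", "full"}
            assert row["BAM"] == "NA"
            assert int(row["Lane"]) == lanes_seen.get(row["Sample_Name"], 0) + 1
            lanes_seen[row["Sample_Name"]] = int(row["Lane"])


class TestBibliography:
    def test_samples_sharing_a_doi_give_one_entry(self):
        b = generate_dataset(3, 1, seed=4)
        doi_idx = b.samples.column_index("publication_doi")
        for row in b.samples.rows:
            row[doi_idx] = "10.99999/shared.doi"
        bib = make_bibliography(b.samples)
        assert bib.count("@misc") == 1
        assert "10.99999/shared.doi" in bib

    def test_empty_subset_gives_empty_bibliography(self, samples_schema):
        empty = MetadataTable(list(samples_schema.column_names), [])
        assert make_bibliography(empty) == ""

    def test_distinct_dois_give_distinct_sorted_keys(self):
        b = generate_dataset(12, 1, seed=6)
        dois = set(b.samples.column("publication_doi"))
        bib = make_bibliography(b.samples)
        assert bib.count("@misc") == len(dois)  # distinct-count oracle
        keys = [
            line.split("{")[1].rstrip(",")
            for line in bib.split("\n")
            if line.startswith("@misc")
        ]
        assert keys == sorted(keys) and len(set(keys)) == len(keys)


class TestExportTables:
    def test_four_artefacts_written_with_canonical_names(self, bundle, tmp_path):
        written = export_tables(
            bundle.samples, bundle.libraries, tmp_path,
            curl=True, eager=True, bibliography=True, librarymetadata=True,
        )
        assert sorted(p.name for p in written) == sorted(
            [
                DOWNLOAD_SCRIPT_NAME.format(tool="curl"),
                EAGER_SHEET_NAME,
                BIBLIOGRAPHY_NAME,
                FILTERED_LIBRARIES_NAME,
            ]
        )

    def test_rerun_is_byte_identical(self, bundle, tmp_path):
        kwargs = dict(curl=True, eager=True, bibliography=True, librarymetadata=True)
        first = {
            p.name: p.read_bytes()
            for p in export_tables(bundle.samples, bundle.libraries, tmp_path / "a", **kwargs)
        }
        second = {
            p.name: p.read_bytes()
            for p in export_tables(bundle.samples, bundle.libraries, tmp_path / "b", **kwargs)
        }
        assert first == second


class TestFilterConvertCommutativity:
    def test_script_from_prefiltered_equals_filter_then_convert(self, bundle):
        expr = parse_expression("publication_year>=2020")
        selected_samples = filter_table(bundle.samples, expr)
        via_join = make_download_script(
            join_libraries(selected_samples, bundle.libraries)
        ).text()
        # independent pre-filtering of the libraries table by sample accession
        keep = {
            tok
            for cell in selected_samples.column("archive_accession")
            for tok in cell.split(";")
        }
        acc_idx = bundle.libraries.column_index("archive_sample_accession")
        prefiltered = MetadataTable(
            list(bundle.libraries.header),
            [r for r in bundle.libraries.rows if set(r[acc_idx].split(";")) & keep],
            schema=bundle.libraries.schema,
        )
        assert make_download_script(prefiltered).text() == via_join


class TestMergeTables:
    def _split(self, bundle, n):
        t = bundle.samples
        a = MetadataTable(list(t.header), [list(r) for r in t.rows[:n]], schema=t.schema)
        b = MetadataTable(list(t.header), [list(r) for r in t.rows[n:]], schema=t.schema)
        return a, b

    def test_disjoint_tables_concatenate_existing_first(self, bundle):
        a, b = self._split(bundle, 3)
        merged = merge_tables(a, b)
        assert merged.rows[:3] == a.rows and merged.rows[3:] == b.rows

    def test_colliding_key_is_a_merge_error_naming_it(self, bundle):
        a, b = self._split(bundle, 10)
        dup_name = a.cell(2, "sample_name")
        b.rows[0][b.column_index("sample_name")] = dup_name
        with pytest.raises(MergeError, match=dup_name):
            merge_tables(a, b)

    def test_header_mismatch_is_a_merge_error(self, bundle, samples_schema):
        a, b = self._split(bundle, 3)
        swapped = list(b.header)
        swapped[0], swapped[1] = swapped[1], swapped[0]
        rows = [
            [row[b.header.index(c)] for c in swapped] for row in b.rows
        ]
        odd = MetadataTable(swapped, rows)
        with pytest.raises(MergeError, match="header"):
            merge_tables(a, odd, samples_schema)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_merged_keys_are_the_set_union(self, seed):
        x = generate_dataset(8, 1, seed=seed)
        y = generate_dataset(8, 1, seed=seed + 100)
        # make y's keys disjoint from x's
        idx = y.samples.column_index("sample_name")
        for i, row in enumerate(y.samples.rows):
            row[idx] = f"OTHER{i:03d}"
        merged = merge_tables(x.samples, y.samples)
        assert set(merged.column("sample_name")) == set(
            x.samples.column("sample_name")
        ) | set(y.samples.column("sample_name"))
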