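"""Filtering, joining and selection-summary semantics."""

import random

import pytest

from amdir import (
    FilterExpression,
    MetadataTable,
    Predicate,
    UsageError,
    filter_table,
    generate_dataset,
    join_libraries,
    parse_expression,
    summarize_selection,
)


def _expr(*clauses):
    return FilterExpression(tuple(clauses))


class TestFilterTable:
    def test_spain_since_2020_worked_example(self):
        table = MetadataTable(
            ["publication_year", "geo_loc_name"],
            [["2019", "Spain"], ["2021", "Spain"], ["2021", "Germany"]],
        )
        expr = _expr(
            (Predicate("publication_year", "ge", 2020), "AND"),
            (Predicate("geo_loc_name", "eq", "Spain"), "AND"),
        )
        result = filter_table(table, expr)
        assert result.rows == [["2021", "Spain"]]

    def test_empty_expression_selects_all_rows(self, bundle):
        result = filter_table(bundle.samples, FilterExpression())
        assert result.rows == bundle.samples.rows

    def test_unknown_column_is_usage_error_listing_candidates(self, bundle):
        with pytest.raises(UsageError, match="geo_loc_name"):
            filter_table(bundle.samples, _expr((Predicate("geo", "eq", "x"), "AND")))

    def test_missing_token_never_satisfies_numeric_predicates(self):
        table = MetadataTable(["sample_age"], [["unknown"], ["100"]])
        result = filter_table(table, _expr((Predicate("sample_age", "ge", 0), "AND")))
        assert result.rows == [["100"]]

    def test_or_connective_widens_within_a_column(self):
        table = MetadataTable(["geo_loc_name"], [["Spain"], ["Germany"], ["France"]])
        expr = _expr(
            (Predicate("geo_loc_name", "eq", "Spain"), "AND"),
            (Predicate("geo_loc_name", "eq", "France"), "OR"),
        )
        assert filter_table(table, expr).rows == [["Spain"], ["France"]]

    def test_idempotence(self, bundle):
        expr = parse_expression("geo_loc_name=Spain & publication_year>=2020")
        once = filter_table(bundle.samples, expr)
        twice = filter_table(once, expr)
        assert twice.rows == once.rows

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_expressions_match_bruteforce_row_scan(self, seed):
        rng = random.Random(seed)
        b = generate_dataset(100, (1, 3), seed=seed)  # 200-ish row scale
        table = b.samples
        ops = ["eq", "ne", "contains", "ge", "le", "gt", "lt"]
        clauses = []
        for _ in range(rng.randint(1, 4)):
            col = rng.choice(["publication_year", "geo_loc_name", "sample_age"])
            if col == "geo_loc_name":
                op = rng.choice(["eq", "ne", "contains"])
                operand = rng.choice(["Spain", "Germany", "an"])
            else:
                op = rng.choice(ops[3:])
                operand = rng.choice([2018, 2020, 5000])
            clauses.append((Predicate(col, op, operand), rng.choice(["AND", "OR"])))
        expr = FilterExpression(tuple(clauses))

        # oracle: naive per-row evaluation, independent of filter_table
        def naive_keep(row):
            per_column = {}
            for pred, conn in clauses:
                cell = row[table.column_index(pred.column)]
                if pred.op in ("ge", "le", "gt", "lt"):
                    try:
                        v = float(cell)
                        hit = {
                            "ge": v >= pred.operand,
                            "le": v <= pred.operand,
                            "gt": v > pred.operand,
                            "lt": v < pred.operand,
                        }[pred.op]
                    except ValueError:
                        hit = False
                elif pred.op == "eq":
                    hit = cell == pred.operand
                elif pred.op == "ne":
                    hit = cell != pred.operand
                else:
                    hit = pred.operand in cell
                if pred.column not in per_column:
                    per_column[pred.column] = hit
                elif conn == "AND":
                    per_column[pred.column] = per_column[pred.column] and hit
                else:
                    per_column[pred.column] = per_column[pred.column] or hit
            return all(per_column.values())

        expected = [row for row in table.rows if naive_keep(row)]
        assert filter_table(table, expr).rows == expected


class TestJoinLibraries:
    def test_selected_samples_bring_all_their_libraries(self):
        b = generate_dataset(2, 2, seed=1)
        subset = b.samples
        joined = join_libraries(subset, b.libraries)
        assert len(joined) == 4

    def test_empty_subset_gives_header_only_table(self, bundle):
        empty = MetadataTable(
            list(bundle.samples.header), [], schema=bundle.samples.schema
        )
        joined = join_libraries(empty, bundle.libraries)
        assert joined.header == bundle.libraries.header
        assert joined.rows == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_join_equals_nested_loop_oracle(self, seed):
        rng = random.Random(seed)
        b = generate_dataset(30, (1, 3), seed=seed)
        keep = sorted(rng.sample(range(len(b.samples.rows)), 10))
        subset = MetadataTable(
            list(b.samples.header),
            [list(b.samples.rows[i]) for i in keep],
            schema=b.samples.schema,
        )
        joined = join_libraries(subset, b.libraries)
        # oracle: nested loop over library x sample accession containment
        acc_idx = b.samples.column_index("archive_accession")
        lib_acc_idx = b.libraries.column_index("archive_sample_accession")
        expected = [
            row
            for row in b.libraries.rows
            if any(
                row[lib_acc_idx] in subset.rows[i][acc_idx].split(";")
                for i in range(len(subset.rows))
            )
        ]
        assert joined.rows == expected

    def test_join_conservation_no_duplicates_and_keys_in_subset(self, bundle):
        joined = join_libraries(bundle.samples, bundle.libraries)
        names = joined.column("library_name")
        assert len(names) == len(set(names))
        sample_accs = {
            tok
            for cell in bundle.samples.column("archive_accession")
            for tok in cell.split(";")
        }
        for cell in joined.column("archive_sample_accession"):
            assert set(cell.split(";")) & sample_accs

    def test_unbound_tables_are_usage_error(self, bundle):
        bare = MetadataTable(list(bundle.samples.header), [])
        with pytest.raises(UsageError):
            join_libraries(bare, bundle.libraries)


class TestSummarizeSelection:
    def test_two_rows_sum_to_600_bytes(self, libraries_schema):
        header = list(libraries_schema.column_names)
        template = {c: "" for c in header}
        rows = []
        for sizes, acc in (("100;200", "ERR3000001"), ("300", "ERR3000002")):
            cells = dict(template)
            cells["download_sizes"] = sizes
            cells["archive_data_accession"] = acc
            rows.append([cells[c] for c in header])
        table = MetadataTable(header, rows)
        summary = summarize_selection(table)
        assert (summary.n_rows, summary.n_runs, summary.total_bytes) == (2, 2, 600)

    def test_empty_selection_is_all_zeros(self, libraries_schema):
        table = MetadataTable(list(libraries_schema.column_names), [])
        summary = summarize_selection(table)
        assert (summary.n_rows, summary.n_runs, summary.total_bytes) == (0, 0, 0)

    def test_fixture_total_equals_flat_summation_oracle(self, bundle):
        summary = summarize_selection(bundle.libraries)
        flat = sum(
            int(tok)
            for cell in bundle.libraries.column("download_sizes")
            for tok in cell.split(";")
        )
        assert summary.total_bytes == flat

    def test_unparseable_size_cell_names_its_line(self, bundle):
        bundle.libraries.rows[1][
            bundle.libraries.column_index("download_sizes")
        ] = "lots"
        with pytest.raises(UsageError, match="line 3"):
            summarize_selection(bundle.libraries)


class TestExpressionSyntax:
    def test_worked_example_string_form(self):
        expr = parse_expression("geo_loc_name=Spain & publication_year>=2020")
        assert len(expr.clauses) == 2
        assert expr.clauses[0][0].op == "eq"
        assert expr.clauses[1][0].op == "ge"
        assert expr.clauses[1][0].operand == 2020.0

    def test_quoted_values_and_contains(self):
        expr = parse_expression("site_name~'Cave' | site_name=\"Abri\"")
        assert expr.clauses[0][0].op == "contains"
        assert expr.clauses[1][1] == "OR"

    @pytest.mark.parametrize("bad", ["geo_loc_name", "=Spain", "year>=x", "a=1 & "])
    def test_malformed_expressions_rejected(self, bad):
        with pytest.raises(UsageError):
            parse_expression(bad)

    def test_empty_expression_selects_everything(self, bundle):
        assert (
            filter_table(bundle.samples, parse_expression("")).rows
            == bundle.samples.rows
        )
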