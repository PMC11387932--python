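# amdir

A curation toolkit for the sample- and library-level metadata tables of
community-curated ancient-metagenomics directories (the
AncientMetagenomeDir dialect): plain TSV tables describing ancient
host-associated metagenomes, ancient microbial single genomes, and ancient
environmental metagenomes, validated against JSON schemas with JSON enum
vocabularies.

## Why

Reusing published ancient DNA (aDNA) sequencing data needs more than a run
accession.  Correct reprocessing depends on library-level facts the
sequencing archives only partially record: whether a library was built
double- or single-stranded, whether deaminated bases were removed with
Uracil-DNA Glycosylase (none / half / full UDG treatment), the indexing
polymerase, the sequencing instrument (2- vs 4-colour chemistry decides
whether poly-G trimming is needed), layout (single- vs paired-end), plus
the FASTQ URLs, md5 checksums and download sizes needed to actually get the
data.  This package implements the machinery around such a directory for
three audiences:

* **contributors** — `autofill` queries the ENA portal API's read_run
  report and drafts a library table, leaving the aDNA-specific columns as
  `unknown` for manual curation;
* **curators/CI** — `validate` checks a submission cell-by-cell against
  the schemas and cross-references DOIs, INSDC accessions, duplicates, and
  sample↔library↔project consistency, reporting every defect with its
  line, column, explanation and fix hint (exit code 0 iff clean);
* **data users** — `filter`/`convert` select samples, pull in their
  libraries, and emit a curl/wget download script with an md5 verification
  block, an nf-core/eager input-sheet template, a BibTeX citation file and
  the filtered library table.

A seeded fixture generator (`amdir.fixtures`) produces schema-valid
synthetic datasets and systematically corrupted variants with a manifest of
every planted error; the validator is tested to reproduce those manifests
exactly (full recall, zero false positives).

## Worked example

Generate a small synthetic directory, select host-associated samples from
Spain published since 2020, and build their download script — the same
pipeline the CLI runs:

```python
from amdir import (
    generate_dataset, parse_expression, filter_table,
    join_libraries, summarize_selection, make_download_script,
)

bundle = generate_dataset(20, (1, 3), seed=42)      # 20 samples, 41 libraries
expr = parse_expression("geo_loc_name=Spain & publication_year>=2020")
selected = filter_table(bundle.samples, expr)        # 2 samples
libraries = join_libraries(selected, bundle.libraries)   # their 4 libraries
summary = summarize_selection(libraries)
print(len(selected), len(libraries), summary.n_runs, summary.human_size())
# 2 4 4 1.8 GB
script = make_download_script(libraries, "curl")
print(script.text()[:160])
# #!/usr/bin/env bash
# set -euo pipefail
#
# # 5 file(s) selected from library metadata
# curl -L -o 'ERR3000032_1.fastq.gz' 'https://ftp.fixture.invalid/...'
```

The 2 selected samples carry 4 libraries whose 4 runs comprise 5 FASTQ
files (paired-end runs contribute two files); downloading them would use
1.8 GB, and the script ends with an `md5sum -c` block covering each file
exactly once.

The same flow from the shell, given tables on disk:

```bash
amdir download --table ancientmetagenome-hostassociated --table_type samples \
      --release v24.03.0
amdir filter ancientmetagenome-hostassociated_samples_v24.03.0.tsv \
      -e "geo_loc_name=Spain & publication_year>=2020" -o spain.tsv
amdir convert --curl --eager --bibliography --librarymetadata \
      spain.tsv ancientmetagenome-hostassociated --release v24.03.0 -o out/
```

`convert` writes `AncientMetagenomeDir_curl_download_script.sh`,
`AncientMetagenomeDir_nf_core_eager_input_table.tsv`,
`AncientMetagenomeDir_bibliography.bib` and
`AncientMetagenomeDir_filtered_libraries.tsv`.  The eager sheet is a
*template*: archive metadata is heterogeneous, so review it before running
a pipeline on it.

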