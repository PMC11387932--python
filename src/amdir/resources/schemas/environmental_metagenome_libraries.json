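{
  "dataset_kind": "environmental_metagenome",
  "table_type": "libraries",
  "key_columns": [
    "library_name"
  ],
  "columns": [
    {
      "name": "project_name",
      "value_kind": "free_text",
      "required": true
    },
    {
      "name": "publication_year",
      "value_kind": "integer",
      "required": true
    },
    {
      "name": "publication_doi",
      "value_kind": "doi",
      "required": true
    },
    {
      "name": "sample_name",
      "value_kind": "free_text",
      "required": true
    },
    {
      "name": "archive",
      "value_kind": "enum",
      "required": true,
      "enum_ref": "archive"
    },
    {
      "name": "archive_project",
      "value_kind": "accession_list",
      "required": true
    },
    {
      "name": "archive_sample_accession",
      "value_kind": "accession_list",
      "required": true
    },
    {
      "name": "library_name",
      "value_kind": "free_text",
      "required": true
    },
    {
      "name": "strand_type",
      "value_kind": "enum",
      "required": true,
      "enum_ref": "strand_type"
    },
    {
      "name": "library_polymerase",
      "value_kind": "enum",
      "required": true,
      "enum_ref": "library_polymerase"
    },
    {
      "name": "library_treatment",
      "value_kind": "enum",
      "required": true,
      "enum_ref": "library_treatment"
    },
    {
      "name": "instrument_model",
      "value_kind": "enum",
      "required": true,
      "enum_ref": "instrument_model"
    },
    {
      "name": "library_layout",
      "value_kind": "enum",
      "required": true,
      "enum_ref": "library_layout"
    },
    {
      "name": "library_strategy",
      "value_kind": "enum",
      "required": true,
      "enum_ref": "library_strategy"
    },
    {
      "name": "read_count",
      "value_kind": "integer",
      "required": true
    },
    {
      "name": "archive_data_accession",
      "value_kind": "accession_list",
      "required": true
    },
    {
      "name": "download_links",
      "value_kind": "url_list",
      "required": true
    },
    {
      "name": "download_md5s",
      "value_kind": "md5_list",
      "required": true
    },
    {
      "name": "download_sizes",
      "value_kind": "byte_size_list",
      "required": true
    }
  ]
}
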