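{
  "dataset_kind": "environmental_metagenome",
  "table_type": "samples",
  "key_columns": [
    "sample_name"
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
      "name": "site_name",
      "value_kind": "free_text",
      "required": true,
      "missing_token_allowed": true
    },
    {
      "name": "latitude",
      "value_kind": "number",
      "required": true,
      "missing_token_allowed": true
    },
    {
      "name": "longitude",
      "value_kind": "number",
      "required": true,
      "missing_token_allowed": true
    },
    {
      "name": "geo_loc_name",
      "value_kind": "free_text",
      "required": true
    },
    {
      "name": "sample_name",
      "value_kind": "free_text",
      "required": true
    },
    {
      "name": "depth",
      "value_kind": "number",
      "required": true,
      "missing_token_allowed": true
    },
    {
      "name": "sample_age",
      "value_kind": "integer",
      "required": true,
      "missing_token_allowed": true
    },
    {
      "name": "sample_age_doi",
      "value_kind": "doi",
      "required": false,
      "missing_token_allowed": true
    },
    {
      "name": "feature",
      "value_kind": "free_text",
      "required": true,
      "missing_token_allowed": true
    },
    {
      "name": "material",
      "value_kind": "enum",
      "required": true,
      "enum_ref": "material"
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
      "name": "archive_accession",
      "value_kind": "accession_list",
      "required": true
    }
  ]
}
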