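[
  "dental calculus",
  "tooth",
  "bone",
  "coprolite",
  "palaeofaeces",
  "sediment",
  "mummified tissue",
  "shell",
  "other",
  "unknown"
]
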