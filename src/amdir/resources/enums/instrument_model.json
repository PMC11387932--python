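[
  "Illumina HiSeq 2500",
  "Illumina HiSeq 4000",
  "Illumina MiSeq",
  "Illumina NovaSeq 6000",
  "NextSeq 500",
  "NextSeq 2000",
  "HiSeq X Ten",
  "Illumina Genome Analyzer II",
  "unknown"
]
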