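{
  "standard": "plant type IIS common syntax (Phytobricks-compatible); 12 fusion sites",
  "comment": "fusion_sites enumerates the 12 standard 4-nt overhangs left-to-right along a transcription unit; positions maps part_type[:fusion_mode] to its (5', 3') junction sites. Replace this file to use a different syntax.",
  "enzyme": {"name": "BsaI", "recognition": "GGTCTC"},
  "spacer": "A",
  "fusion_sites": {
    "A1": "GGAG",
    "A2": "TGAC",
    "A3": "TCCC",
    "B1": "TACT",
    "B2": "CCAT",
    "B3": "AATG",
    "B4": "AGCC",
    "B5": "TTCG",
    "B6": "GCTT",
    "C1": "GGTA",
    "C2": "CGCT",
    "C3": "GTTT"
  },
  "positions": {
    "promoter": ["GGAG", "AATG"],
    "utr5": ["CCAT", "AATG"],
    "cds:no_fusion": ["AATG", "GCTT"],
    "cds:c_terminal": ["AATG", "TTCG"],
    "cds:n_terminal": ["AGCC", "GCTT"],
    "utr3": ["GCTT", "GGTA"],
    "terminator": ["GGTA", "CGCT"]
  }
}
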