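{
  "numbering": "precursor light-chain numbering, 1-based, starting at the first residue after the cleaved signal sequence",
  "fibril_protein_span": {"start": 2, "end": 116, "label": "fibril protein (Ser2-Ser116)"},
  "conformations": {
    "A": {
      "ordered_spans": [
        {"start": 9, "end": 49, "label": "ordered core 1 (Ala9-Arg49)"},
        {"start": 60, "end": 107, "label": "ordered core 2 (Arg60-Val107)"}
      ],
      "disordered_spans": [
        {"start": 2, "end": 8, "label": "N-terminus (Ser2-Pro8)"},
        {"start": 50, "end": 59, "label": "internal disorder (Lys50-Asp59)"},
        {"start": 108, "end": 116, "label": "C-terminus (Leu108-Ser116)"}
      ],
      "strand_spans": [
        {"start": 10, "end": 14, "label": "b1"},
        {"start": 17, "end": 23, "label": "b2"},
        {"start": 25, "end": 26, "label": "b3"},
        {"start": 28, "end": 31, "label": "b4"},
        {"start": 34, "end": 37, "label": "b5"},
        {"start": 43, "end": 47, "label": "b6"},
        {"start": 60, "end": 62, "label": "b6p"},
        {"start": 64, "end": 65, "label": "b6pp"},
        {"start": 72, "end": 75, "label": "b7"},
        {"start": 79, "end": 82, "label": "b8"},
        {"start": 85, "end": 86, "label": "b9"},
        {"start": 88, "end": 91, "label": "b10"},
        {"start": 95, "end": 97, "label": "b11"},
        {"start": 103, "end": 106, "label": "b12"}
      ]
    },
    "B": {
      "ordered_spans": [
        {"start": 9, "end": 49, "label": "ordered core 1 (Ala9-Arg49)"},
        {"start": 68, "end": 107, "label": "ordered core 2 (Asn68-Val107)"}
      ],
      "disordered_spans": [
        {"start": 2, "end": 8, "label": "N-terminus (Ser2-Pro8)"},
        {"start": 50, "end": 67, "label": "internal disorder (Lys50-Gly67)"},
        {"start": 108, "end": 116, "label": "C-terminus (Leu108-Ser116)"}
      ],
      "strand_spans": [
        {"start": 10, "end": 14, "label": "b1"},
        {"start": 17, "end": 23, "label": "b2"},
        {"start": 25, "end": 26, "label": "b3"},
        {"start": 28, "end": 31, "label": "b4"},
        {"start": 34, "end": 37, "label": "b5"},
        {"start": 43, "end": 47, "label": "b6"},
        {"start": 72, "end": 75, "label": "b7"},
        {"start": 79, "end": 82, "label": "b8"},
        {"start": 85, "end": 86, "label": "b9"},
        {"start": 88, "end": 91, "label": "b10"},
        {"start": 95, "end": 97, "label": "b11"},
        {"start": 103, "end": 106, "label": "b12"}
      ]
    }
  },
  "mutations": [
    {"position": 31, "from_aa": "Y", "to_aa": "S", "germline_segment": "IGLV3-19"},
    {"position": 48, "from_aa": "Y", "to_aa": "F", "germline_segment": "IGLV3-19"},
    {"position": 49, "from_aa": "G", "to_aa": "R", "germline_segment": "IGLV3-19"},
    {"position": 51, "from_aa": "N", "to_aa": "S", "germline_segment": "IGLV3-19"},
    {"position": 94, "from_aa": "G", "to_aa": "A", "germline_segment": "IGLV3-19"},
    {"position": 97, "from_aa": "V", "to_aa": "Q", "germline_segment": "IGLJ2"},
    {"position": 135, "from_aa": "V", "to_aa": "G", "germline_segment": "IGLC2"}
  ]
}
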