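{
  "version": "1.0",
  "comment": "Motif and signature-residue coordinates of the TsaC/Sua5 family in a fixed reference numbering. The two reference chains shipped with the package are SYNTHETIC templates built deterministically from these coordinates (real UniProt reference sequences are not redistributed); the coordinate layout follows the Pa-Sua5 / Ec-TsaC numbering convention, with the catalytic Ser-x-Asn pair placed at 139/141 so it does not collide with the signature position 143.",
  "references": {
    "Pa-Sua5": {
      "length": 340,
      "tetrad": {"K": 56, "R": 58, "S": 139, "N": 141},
      "threonine_site": {"T": 33, "S": 181, "R": 195},
      "sua5_specific": {"P59": 59, "N62": 62, "H67": 67, "P142": 142, "H157": 157, "D161": 161},
      "kpspt_motif": {"start": 149, "residues": ["KR", "P", "S", "P", "T"]},
      "gve_motif": {"start": 178, "residues": ["G", "VIL", "E"]},
      "loop_motifs": {"PGM": {"start": 228, "residues": ["P", "G", "M"]}, "HY": {"start": 234, "residues": ["H", "Y"]}},
      "sua5_domain_args": {"R301": 301, "R328": 328},
      "signature": {"position": 143, "expected": "P"},
      "catalytic_span": [1, 215],
      "loop_span": [216, 240],
      "sua5_domain_span": [241, 340]
    },
    "Ec-TsaC": {
      "length": 190,
      "tetrad": {"K": 56, "R": 58, "S": 134, "N": 136},
      "threonine_site": {"T": 33, "S": 176, "R": 190},
      "signature": {"position": 138, "expected": "TS"},
      "catalytic_span": [1, 190]
    }
  }
}
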