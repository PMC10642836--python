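{
  "pathways": {
    "MAPK": {
      "nodes": {
        "NGF": ["NGF"],
        "NT3/4": ["NTF3", "NTF4"],
        "EGF": ["EGF"],
        "PDGF": ["PDGFA", "PDGFB"],
        "PDGFR": ["PDGFRA", "PDGFRB"],
        "IGF-1R": ["IGF1R"],
        "SOS": ["SOS1", "SOS2"],
        "RAS": ["HRAS", "KRAS", "NRAS"],
        "MEK": ["MAP2K1", "MAP2K2"],
        "MEKK1": ["MAP3K1"],
        "JNK": ["MAPK8", "MAPK9", "MAPK10"],
        "c-JUN": ["JUN"],
        "Myc": ["MYC"],
        "FASL": ["FASLG"],
        "TNF": ["TNF"],
        "DAXX": ["DAXX"],
        "CASP": ["CASP3", "CASP8", "CASP9"],
        "P53": ["TP53"]
      }
    },
    "PI3K_AKT": {
      "nodes": {
        "EGF": ["EGF"],
        "PDGF": ["PDGFA", "PDGFB"],
        "ITG-A": ["ITGA1", "ITGA2", "ITGA4"],
        "ITG-B": ["ITGB1", "ITGB3"],
        "PI3K": ["PIK3CA", "PIK3CB", "PIK3CD", "PIK3R1"],
        "PTEN": ["PTEN"],
        "GSK-3b": ["GSK3B"],
        "Bcl-2": ["BCL2"],
        "Bcl-xL": ["BCL2L1"],
        "MEK": ["MAP2K1", "MAP2K2"],
        "Myc": ["MYC"],
        "p21": ["CDKN1A"],
        "CDK4/6": ["CDK4", "CDK6"],
        "CycD": ["CCND1", "CCND2", "CCND3"]
      }
    },
    "CELL_CYCLE": {
      "nodes": {
        "TGF-b": ["TGFB1", "TGFB2"],
        "SMAD2/3": ["SMAD2", "SMAD3"],
        "P15": ["CDKN2B"],
        "P19": ["CDKN2D"],
        "CDK4/6": ["CDK4", "CDK6"],
        "CycD": ["CCND1", "CCND2", "CCND3"],
        "E2F1/2/3": ["E2F1", "E2F2", "E2F3"],
        "P300": ["EP300"],
        "P53": ["TP53"],
        "p21": ["CDKN1A"],
        "Bcl-2": ["BCL2"],
        "Bcl-xL": ["BCL2L1"]
      }
    }
  }
}
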