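{
  "_comment": "Approximate GRCh38 chromosome lengths and centromere midpoints (bp), used to assign chromosome arms to copy-number segments. Karyotype comparison works at arm level, so approximation is sufficient.",
  "chr1": {"length": 248956422, "centromere": 123400000},
  "chr2": {"length": 242193529, "centromere": 93900000},
  "chr3": {"length": 198295559, "centromere": 90900000},
  "chr4": {"length": 190214555, "centromere": 50000000},
  "chr5": {"length": 181538259, "centromere": 48800000},
  "chr6": {"length": 170805979, "centromere": 59800000},
  "chr7": {"length": 159345973, "centromere": 60100000},
  "chr8": {"length": 145138636, "centromere": 45200000},
  "chr9": {"length": 138394717, "centromere": 43000000},
  "chr10": {"length": 133797422, "centromere": 39800000},
  "chr11": {"length": 135086622, "centromere": 53400000},
  "chr12": {"length": 133275309, "centromere": 35500000},
  "chr13": {"length": 114364328, "centromere": 17700000},
  "chr14": {"length": 107043718, "centromere": 17200000},
  "chr15": {"length": 101991189, "centromere": 19000000},
  "chr16": {"length": 90338345, "centromere": 36800000},
  "chr17": {"length": 83257441, "centromere": 25100000},
  "chr18": {"length": 80373285, "centromere": 18500000},
  "chr19": {"length": 58617616, "centromere": 26200000},
  "chr20": {"length": 64444167, "centromere": 28100000},
  "chr21": {"length": 46709983, "centromere": 12000000},
  "chr22": {"length": 50818468, "centromere": 15000000},
  "chrX": {"length": 156040895, "centromere": 61000000},
  "chrY": {"length": 57227415, "centromere": 10400000}
}
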