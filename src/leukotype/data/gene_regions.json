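{
  "_comment": "Approximate GRCh38 gene spans (1-based, whole locus) for genes referenced by the rule engine, fixtures and simulator. Resolution requirements are coarse (enhancer windows are hundreds of kb), so locus-level approximation is sufficient.",
  "MECOM": ["chr3", 169083499, 169663007],
  "GATA2": ["chr3", 128479427, 128493201],
  "CDK6": ["chr7", 92604921, 92836594],
  "HOXA13": ["chr7", 27193337, 27200265],
  "HOXA10": ["chr7", 27170591, 27180261],
  "BCL11B": ["chr14", 99169287, 99272197],
  "TLX3": ["chr5", 171299192, 171302355],
  "NKX2-5": ["chr5", 173232104, 173235307],
  "KMT2A": ["chr11", 118436492, 118526832],
  "FLT3": ["chr13", 28003274, 28100592],
  "RUNX1": ["chr21", 34787801, 35049344],
  "RUNX1T1": ["chr8", 91954967, 92103287],
  "CBFB": ["chr16", 67029149, 67101058],
  "MYH11": ["chr16", 15703135, 15857033],
  "NPM1": ["chr5", 171387116, 171411137],
  "TP53": ["chr17", 7668402, 7687550],
  "NUP98": ["chr11", 3726595, 3867655],
  "NSD1": ["chr5", 177133024, 177300213],
  "KDM5A": ["chr12", 280057, 389320],
  "DEK": ["chr6", 18224099, 18265054],
  "NUP214": ["chr9", 131125587, 131233545],
  "PML": ["chr15", 73994673, 74047827],
  "RARA": ["chr17", 40309180, 40357643],
  "RARB": ["chr3", 25174330, 25597932],
  "TBL1XR1": ["chr3", 177019341, 177228000],
  "RBM15": ["chr1", 110338506, 110346681],
  "MRTFA": ["chr22", 40406355, 40632741],
  "MLLT3": ["chr9", 20341669, 20622499],
  "MLLT10": ["chr10", 21524646, 21743630],
  "MLLT1": ["chr19", 6210374, 6279959],
  "MLLT4": ["chr6", 167826991, 167970655],
  "MLLT6": ["chr17", 38851458, 38869859],
  "MLLT11": ["chr1", 151062556, 151067694],
  "ELL": ["chr19", 18442854, 18522140],
  "CEBPA": ["chr19", 33299934, 33302534],
  "GATA1": ["chrX", 48786562, 48794311],
  "CBL": ["chr11", 119206298, 119308149],
  "PICALM": ["chr11", 85957172, 86069882],
  "KAT6A": ["chr8", 41929478, 42051997],
  "CREBBP": ["chr16", 3725054, 3880713],
  "FUS": ["chr16", 31180110, 31194871],
  "ERG": ["chr21", 38380027, 38661780],
  "CBFA2T3": ["chr16", 88868055, 88941263],
  "GLIS2": ["chr16", 4251369, 4259782],
  "MYB": ["chr6", 135181315, 135219173],
  "TEC": ["chr4", 48137520, 48271925],
  "HSPA8": ["chr11", 123057489, 123063230],
  "PRDM16": ["chr1", 3069203, 3438621],
  "EVX1": ["chr7", 27241988, 27247149],
  "POU2F2": ["chr19", 41925178, 42005265],
  "ZEB2": ["chr2", 144384081, 144512601],
  "USP42": ["chr7", 6102853, 6158422],
  "KIT": ["chr4", 54657918, 54740715],
  "CNTRL": ["chr9", 121099847, 121343541]
}
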