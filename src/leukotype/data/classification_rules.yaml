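# Molecular classification pattern sets for pediatric AML.
#
# This file is deliberately data, not code: new diagnostic markers are
# adopted by editing the pattern lists, without touching the rule engine.
# Tier membership of recently described lesions is editable; the engine
# only requires the tiers to be disjoint.
#
# Pattern syntax for fusions/rearrangements:
#   GENEA::GENEB   exact 5'::3' partner pair
#   GENE::*        any fusion with GENE as 5' partner (likewise *::GENE)
#   GENE-r         any rearrangement involving GENE, including a
#                  confirmed enhancer-hijack with GENE as target
version: 1

# Tier 2 — AML class-defining gene fusions / rearrangements (WHO 5th ed.)
who_fusions:
  - RUNX1::RUNX1T1
  - CBFB::MYH11
  - PML::RARA
  - TBL1XR1::RARB
  - KMT2A::*
  - NUP98::*
  - MECOM-r
  - DEK::NUP214
  - RBM15::MRTFA

# Tier 3 — AML class-defining gene mutations (WHO 5th ed.)
# TP53-biallelic requires two pathogenic hits (two variants, or a variant
# plus 17p loss, or a variant plus cnLOH over TP53).
who_mutations:
  - NPM1
  - CEBPA-bZIP
  - TP53-biallelic

# Tier 4 — newly proposed / recently recognized class-defining lesions.
proposed_class_fusions:
  - CBFA2T3::GLIS2
  - MYB::GATA1
  - CDK6::HOXA13
  - PICALM::MLLT10
  - KAT6A::CREBBP
  - FUS::ERG
  - RUNX1::CBFA2T3
  - HOXA10-r
  - BCL11B-r
proposed_class_mutations:
  - CBFB-GDXY
  - UBTF-TD

# AML-MR: myelodysplasia-related gene mutations and cytogenetic lesions.
aml_mr_genes:
  - ASXL1
  - BCOR
  - EZH2
  - RUNX1
  - SF3B1
  - SRSF2
  - STAG2
  - U2AF1
  - ZRSR2
aml_mr_cyto:
  - 5q-
  - mono7/7q-
  - 11q-
  - 12p-
  - 17p-
  - i(17q)
  - complex
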