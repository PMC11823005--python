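# Default drug dictionary: generic and brand names per drug class.
# Reconstructed from the published name lists for GLP-1 receptor agonists and
# the comparator antidiabetic / anti-obesity classes; the full proprietary
# name lists are not public, so this file is deliberately user-replaceable
# (pass your own via PipelineConfig.drug_dictionary).
#
# match_mode: "word" (default) matches at word boundaries inside the
# normalized verbatim name; "exact" requires the whole normalized name.
classes:
  GLP-1RA:
    EXENATIDE: {brands: [BYETTA, BYDUREON]}
    LIRAGLUTIDE: {brands: [VICTOZA, SAXENDA]}
    DULAGLUTIDE: {brands: [TRULICITY]}
    SEMAGLUTIDE: {brands: [OZEMPIC, RYBELSUS, WEGOVY]}
    TIRZEPATIDE: {brands: [MOUNJARO]}
  DPP-4 inhibitor:
    SITAGLIPTIN: {brands: [JANUVIA]}
    SAXAGLIPTIN: {brands: [ONGLYZA]}
    LINAGLIPTIN: {brands: [TRADJENTA]}
    ALOGLIPTIN: {brands: [NESINA]}
  sulfonylurea:
    GLIMEPIRIDE: {brands: [AMARYL]}
    GLIPIZIDE: {brands: [GLUCOTROL]}
    GLYBURIDE: {brands: [DIABETA, GLYNASE]}
  metformin:
    METFORMIN: {brands: [GLUCOPHAGE, FORTAMET, GLUMETZA]}
  SGLT2 inhibitor:
    EMPAGLIFLOZIN: {brands: [JARDIANCE]}
    DAPAGLIFLOZIN: {brands: [FARXIGA]}
    CANAGLIFLOZIN: {brands: [INVOKANA]}
  thiazolidinedione:
    PIOGLITAZONE: {brands: [ACTOS]}
    ROSIGLITAZONE: {brands: [AVANDIA]}
  anti-obesity:
    ORLISTAT: {brands: [XENICAL, ALLI]}
    PHENTERMINE: {brands: [ADIPEX-P, LOMAIRA]}
    NALTREXONE-BUPROPION: {brands: [CONTRAVE]}
    PHENTERMINE-TOPIRAMATE: {brands: [QSYMIA]}
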