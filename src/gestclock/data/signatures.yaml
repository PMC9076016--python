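# Built-in gene signatures for PBMC cell-state scoring.
#
# The cytotoxicity set is described in its source as "11 cytotoxicity-
# associated genes" but only 10 symbols are printed, and "KLRDC1" is not a
# standard HGNC symbol (most likely KLRD1).  The 10 printed symbols are kept
# verbatim here; edit to taste.
#
# The ISG set is a documented PLACEHOLDER: the originating 58-gene
# interferon-stimulated-gene list is not printed in its source, so a list of
# canonical ISGs is shipped instead.  All ISG-score operations accept a
# user-supplied list; replace this block to use your own.
#
# GO-pathway sets (e.g. GO:0034340 response to type I interferon,
# GO:0051607 defense response to virus, GO:0042110 T cell activation,
# GO:0042113 B cell activation, GO:0008380 RNA splicing, GO:0000380
# alternative mRNA splicing via spliceosome) must be supplied by the user
# from an ontology export; membership resolution is out of scope.

cytotoxicity:
  role: cytotoxicity
  genes: [PRF1, IFNG, NKG7, GZMB, GZMA, GZMH, KLRK1, KLRDC1, CTSW, CST7]

apoptosis:
  role: apoptosis
  genes: [TNFSF10, TRADD, FAS, FASLG, FADD, TNFSF14, BAD, BAX, CASP4, DAP3, DAXX, PDCD10, PDCD6]

exhaustion:
  role: exhaustion
  genes: [LAG3, PDCD1, CTLA4, HAVCR2, TOX]

isg_placeholder:
  role: ISG
  genes: [STAT1, STAT2, IRF7, IRF9, ISG15, IFI6, IFI27, IFI35, IFI44, IFI44L,
          IFIT1, IFIT2, IFIT3, IFIT5, IFITM1, IFITM2, IFITM3, MX1, MX2,
          OAS1, OAS2, OAS3, OASL, RSAD2, USP18, XAF1, BST2, EIF2AK2, HERC5,
          LY6E, SAMD9, SAMD9L, EPSTI1, PLSCR1, ZBP1, AIM2]
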