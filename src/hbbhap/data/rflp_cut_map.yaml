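# Per-site allele -> restriction-cut symbol used to derive the default
# RFLP +/- pattern table from the haplotype allele table.  The
# orientation (which allele preserves the enzyme recognition site) only
# relabels + and - per column and cannot change which diplotypes are
# distinguishable; set it from the wet-lab assay in use before comparing
# against historically reported +/- patterns.
rs3834466: {G: "+", GT: "-"}
rs28440105: {C: "+", A: "-"}
rs10128556: {C: "-", T: "+"}
rs968857: {T: "+", C: "-"}
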