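# Default tag-variant panel for HBB gene cluster haplotype classification.
# Sites are listed 5' -> 3' across the beta-globin gene cluster; alleles
# are ordered with the REF-by-convention allele first (used when writing
# synthetic VCFs).  Genomic coordinates are deliberately omitted: they
# must be supplied by the user and verified against dbSNP for the VCF
# dialect in hand.  Lookup defaults to the VCF ID column (rsID).
lookup_mode: by_rsid
sites:
  - rsid: rs3834466
    alleles: [G, GT]
    enzyme: "HincII 5' HBE1"
    region: "5' epsilon-globin"
  - rsid: rs28440105
    alleles: [C, A]
    enzyme: "HindIII HBG2"
    region: "G-gamma-globin"
  - rsid: rs10128556
    alleles: [C, T]
    enzyme: "HindIII 3' HBG1"
    region: "A-gamma-globin"
  - rsid: rs968857
    alleles: [T, C]
    enzyme: "HincII 5' HBD"
    region: "3' psi-beta / 5' delta-globin"
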