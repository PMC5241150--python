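# TaqMan probe-panel relative quantities for the two F8-S2 dimeric-gRNA clones,
# all anchored to the unedited control (Ec = 1). Eb: edited + backbone plasmid,
# cut-site (homologous) probe; Ed_hom: edited + donor, homologous probe;
# Ed_het: edited + donor, heterologous probe at the adjacent S1 site.
# The ref_* columns are the originally published repair frequencies, kept for
# comparison against recomputation.
condition,Ec,Eb,Ed_hom,Ed_het,ref_N,ref_HN,ref_HDR_a,ref_HDR_t,ref_pct_HDR_t
pSQT1313-F8S2 Cl.10,1.00,0.32,0.00,0.56,0.68,1.00,0.32,0.44,44.00
pSQT1313-F8S2 Cl.11,1.00,0.49,0.04,0.59,0.51,0.96,0.45,0.41,42.71
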