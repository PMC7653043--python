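# SYNTHETIC placeholder weights for testing the scoring machinery only.
# These are NOT the published East-Asian GWAS beta-coefficients; supply the
# real weight file for any substantive analysis.
rsid,effect_allele,other_allele,beta
rs651007,T,C,0.07
rs599839,A,G,0.09
rs12654264,A,T,0.06
rs2738446,C,G,0.05
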