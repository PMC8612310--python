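# Default pathway-completeness rules: a pathway is complete at a site iff
# every listed gene family is present there.
nitrification: [amoA, amoB, amoC, nxrA, nxrB]
sulfide_oxidation_rdsr: [dsrA, dsrB, dsrE, dsrF, dsrH]
thiosulfate_oxidation_sox: [soxZ, soxX, soxA]
thiosulfate_reduction_phs: [phsA]
anammox: [hzoA, hzsA]
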