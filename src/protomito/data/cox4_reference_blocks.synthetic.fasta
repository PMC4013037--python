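>thermus_caa3_IV_TM1_synthetic synthetic stand-in for subunit IV of the Thermus caa3 oxidase around TM1; block covers subunit positions 8-37 (1-based)
MWKTLGFVALLAGTLYFLWIGLSRPESVQA
>rhodobacter_aa3_IV_TM1_synthetic synthetic stand-in for subunit IV of the Rhodobacter sphaeroides aa3 oxidase around TM1; block covers subunit positions 8-37 (1-based)
MWRSLGIVALIAGSLYALWVGFTKPDAVEA
>thermus_caa3_IV_TM2_synthetic synthetic stand-in for subunit IV of the Thermus caa3 oxidase around TM2 (sole solved 2-TM structure); block covers subunit positions 55-84 (1-based)
PLVIGTFWLAVGLGLALYFMVRESLEEGRH
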