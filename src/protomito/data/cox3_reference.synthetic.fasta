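>beef_COX3_synthetic synthetic stand-in for the mature bovine COX3 reference; 7 transmembrane spans at 6-30,43-67,80-104,117-141,154-178,191-215,228-252 (1-based); phospholipid-site residues planted per the packaged site map
SGNDQLIVFAWLVIRALIVMFLAVILIVYAKTERSHGKQTDKMLVIFALIVMFLAVILIV
FAMLVIFSERSGNDQKTERALIVMFLAVIEWVFAMLVIFALIVMSHGNQTDKSERSFLAV
ILIVFAMLVIFALIVMFLAVIGNDQKTERSHGNLIWFAMYVIFALIVMFLAVILIVFAQT
DKSERSGNDQMLKIFARIVMFLAVILIVFAMLVIFKTERSHGNQTDKALIVMFLAVILIV
FAMLVIFALIVMSERSGNDQK
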