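name,formula
Dihydrobiopterin,C9H13N5O3
PGB2,C20H30O4
Argininosuccinate,C10H18N4O6
CMPF,C12H16O5
Carboxy-LTB4,C20H30O6
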