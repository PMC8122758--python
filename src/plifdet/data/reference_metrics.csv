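receptor,ef,f_measure,f_measure_alt
AA2AR,272.286,0.184,
ADRB2,465.151,0.307,
CXCR4,n.d.,0.333,0.307
DRD3,455.652,0.169,
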