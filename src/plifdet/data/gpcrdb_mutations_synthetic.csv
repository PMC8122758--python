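receptor,residue_number,residue_name,note
AA2AR,169,GLU,
AA2AR,246,TRP,
AA2AR,249,LEU,
AA2AR,250,HIS,
ADRB2,113,ASP,a conserved residue in aminergic GPCRs
ADRB2,204,SER,
ADRB2,312,ASN,
CXCR4,32,GLU,
CXCR4,97,ASP,
CXCR4,255,TYR,
DRD3,110,ASP,a conserved residue in aminergic GPCRs
DRD3,183,ILE,
DRD3,349,HIS,
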