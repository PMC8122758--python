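receptor,descriptor_index,residue_name,residue_number,interaction_type,favorable,verification,note,alt_residue
AA2AR,203,GLU,169,ionic (protein as anion),True,verified,,Glu203
AA2AR,297,TRP,246,aromatic edge-to-face,True,verified,,
AA2AR,316,LEU,249,hydrophobic,False,verified,,
AA2AR,325,HIS,250,aromatic edge-to-face,True,verified,,
ADRB2,31,TRP,109,aromatic edge-to-face,True,n.a.,,
ADRB2,63,ASP,113,ionic (protein as anion),True,verified,a conserved residue in aminergic GPCRs,
ADRB2,155,ASP,192,hydrophobic,False,n.a.,,
ADRB2,163,PHE,193,aromatic face-to-face,True,n.a.,,
ADRB2,207,SER,204,h-bond (protein as donor),True,verified,,
ADRB2,246,TRP,286,hydrophobic,True,n.a.,,
ADRB2,262,PHE,289,aromatic edge-to-face,False,n.a.,,
ADRB2,269,PHE,290,aromatic edge-to-face,True,n.a.,,
ADRB2,326,ASN,312,h-bond (protein as donor),True,verified,,
CXCR4,8,GLU,32,hydrophobic,False,verified,,
CXCR4,99,ASP,97,hydrophobic,True,verified,,
CXCR4,136,TRP,102,aromatic edge-to-face,True,n.a.,,
CXCR4,290,TYR,255,aromatic edge-to-face,True,verified,,
DRD3,43,PHE,106,hydrophobic,True,n.a.,,
DRD3,50,VAL,107,hydrophobic,True,n.a.,,
DRD3,77,ASP,110,ionic (protein as anion),False,verified,a conserved residue in aminergic GPCRs,
DRD3,155,ILE,183,hydrophobic,False,verified,,
DRD3,248,PHE,346,aromatic edge-to-face,True,n.a.,,
DRD3,269,HIS,349,aromatic edge-to-face,True,verified,,
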