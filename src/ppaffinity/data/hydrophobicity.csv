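# Per-residue hydrophobicity scores on a [-1, +2] scale (hydrophilic to
# hydrophobic): the Kyte-Doolittle index affinely rescaled from [-4.5, 4.5]
# via score = (kd + 1.5) / 3.  Terminal residues receive an additive
# modulation applied at aggregation time (see features.hydrophobicity_score).
residue,score
ILE,2.000
VAL,1.900
LEU,1.767
PHE,1.433
CYS,1.333
MET,1.133
ALA,1.100
GLY,0.367
THR,0.267
SER,0.233
TRP,0.200
TYR,0.067
PRO,-0.033
HIS,-0.567
GLU,-0.667
GLN,-0.667
ASP,-0.667
ASN,-0.667
LYS,-0.800
ARG,-1.000
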