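name,role,molar_mass
HEA,monomer,116.12
MA,monomer,86.09
HPA,monomer,130.14
MMA,monomer,100.12
MBiB,initiator,181.03
BPN,initiator,133.98
CuBr2,metal,223.35
Me6TREN,ligand,230.39
PMDETA,ligand,173.30
ZnTPP,photocatalyst,678.11
EosinY,photocatalyst,647.89
DMSO,solvent,78.13
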