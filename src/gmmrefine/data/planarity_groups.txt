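# Planar dihedral groups per residue type (class "other", 10 degree threshold).
# Each row lists a 4-atom torsion whose ideal value is 0 or 180 degrees when
# the group is planar. Peptide omega and carbonyl quads are generated from
# connectivity and are not listed here.
# res a1 a2 a3 a4
PHE CB CG CD1 CE1
PHE CG CD1 CE1 CZ
PHE CD1 CE1 CZ CE2
PHE CE1 CZ CE2 CD2
TYR CB CG CD1 CE1
TYR CG CD1 CE1 CZ
TYR CD1 CE1 CZ CE2
TYR CE1 CZ CE2 CD2
TYR CE1 CZ OH CE2
TRP CB CG CD1 NE1
TRP CG CD1 NE1 CE2
TRP CD1 NE1 CE2 CZ2
TRP NE1 CE2 CD2 CE3
TRP CE2 CD2 CE3 CZ3
TRP CD2 CE3 CZ3 CH2
TRP CE3 CZ3 CH2 CZ2
HIS CB CG ND1 CE1
HIS CG ND1 CE1 NE2
HIS ND1 CE1 NE2 CD2
HIS CE1 NE2 CD2 CG
ARG CD NE CZ NH1
ARG CD NE CZ NH2
ARG NH1 CZ NE NH2
ASN CB CG OD1 ND2
ASP CB CG OD1 OD2
GLN CG CD OE1 NE2
GLU CG CD OE1 OE2
A N9 C8 N7 C5
A C8 N7 C5 C6
A N7 C5 C6 N6
A C4 N9 C8 N7
G N9 C8 N7 C5
G C8 N7 C5 C6
G N7 C5 C6 O6
G C4 N9 C8 N7
C N1 C2 N3 C4
C C2 N3 C4 N4
C N1 C2 O2 N3
U N1 C2 N3 C4
U C2 N3 C4 O4
U N1 C2 O2 N3
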