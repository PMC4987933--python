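# protein pharmacophore typing table, version v1
# residue	atom	classes (comma-separated)
ALA	N	H_DONOR
ALA	CA	HYDROPHOBIC
ALA	C	NEUTRAL
ALA	O	H_ACCEPTOR
ALA	OXT	NEGATIVE,H_ACCEPTOR
ALA	CB	HYDROPHOBIC
ARG	N	H_DONOR
ARG	CA	HYDROPHOBIC
ARG	C	NEUTRAL
ARG	O	H_ACCEPTOR
ARG	OXT	NEGATIVE,H_ACCEPTOR
ARG	CB	HYDROPHOBIC
ARG	CD	HYDROPHOBIC
ARG	CG	HYDROPHOBIC
ARG	CZ	POSITIVE
ARG	NE	POSITIVE,H_DONOR
ARG	NH1	POSITIVE,H_DONOR
ARG	NH2	POSITIVE,H_DONOR
ASN	N	H_DONOR
ASN	CA	HYDROPHOBIC
ASN	C	NEUTRAL
ASN	O	H_ACCEPTOR
ASN	OXT	NEGATIVE,H_ACCEPTOR
ASN	CB	HYDROPHOBIC
ASN	CG	NEUTRAL
ASN	ND2	H_DONOR
ASN	OD1	H_ACCEPTOR
ASP	N	H_DONOR
ASP	CA	HYDROPHOBIC
ASP	C	NEUTRAL
ASP	O	H_ACCEPTOR
ASP	OXT	NEGATIVE,H_ACCEPTOR
ASP	CB	HYDROPHOBIC
ASP	CG	NEUTRAL
ASP	OD1	NEGATIVE,H_ACCEPTOR
ASP	OD2	NEGATIVE,H_ACCEPTOR
CYS	N	H_DONOR
CYS	CA	HYDROPHOBIC
CYS	C	NEUTRAL
CYS	O	H_ACCEPTOR
CYS	OXT	NEGATIVE,H_ACCEPTOR
CYS	CB	HYDROPHOBIC
CYS	SG	SULFUR
GLN	N	H_DONOR
GLN	CA	HYDROPHOBIC
GLN	C	NEUTRAL
GLN	O	H_ACCEPTOR
GLN	OXT	NEGATIVE,H_ACCEPTOR
GLN	CB	HYDROPHOBIC
GLN	CD	NEUTRAL
GLN	CG	HYDROPHOBIC
GLN	NE2	H_DONOR
GLN	OE1	H_ACCEPTOR
GLU	N	H_DONOR
GLU	CA	HYDROPHOBIC
GLU	C	NEUTRAL
GLU	O	H_ACCEPTOR
GLU	OXT	NEGATIVE,H_ACCEPTOR
GLU	CB	HYDROPHOBIC
GLU	CD	NEUTRAL
GLU	CG	HYDROPHOBIC
GLU	OE1	NEGATIVE,H_ACCEPTOR
GLU	OE2	NEGATIVE,H_ACCEPTOR
GLY	N	H_DONOR
GLY	CA	HYDROPHOBIC
GLY	C	NEUTRAL
GLY	O	H_ACCEPTOR
GLY	OXT	NEGATIVE,H_ACCEPTOR
HIS	N	H_DONOR
HIS	CA	HYDROPHOBIC
HIS	C	NEUTRAL
HIS	O	H_ACCEPTOR
HIS	OXT	NEGATIVE,H_ACCEPTOR
HIS	CB	HYDROPHOBIC
HIS	CD2	AROMATIC
HIS	CE1	AROMATIC
HIS	CG	AROMATIC
HIS	ND1	AROMATIC,H_DONOR,H_ACCEPTOR
HIS	NE2	AROMATIC,H_DONOR,H_ACCEPTOR
ILE	N	H_DONOR
ILE	CA	HYDROPHOBIC
ILE	C	NEUTRAL
ILE	O	H_ACCEPTOR
ILE	OXT	NEGATIVE,H_ACCEPTOR
ILE	CB	HYDROPHOBIC
ILE	CD1	HYDROPHOBIC
ILE	CG1	HYDROPHOBIC
ILE	CG2	HYDROPHOBIC
LEU	N	H_DONOR
LEU	CA	HYDROPHOBIC
LEU	C	NEUTRAL
LEU	O	H_ACCEPTOR
LEU	OXT	NEGATIVE,H_ACCEPTOR
LEU	CB	HYDROPHOBIC
LEU	CD1	HYDROPHOBIC
LEU	CD2	HYDROPHOBIC
LEU	CG	HYDROPHOBIC
LYS	N	H_DONOR
LYS	CA	HYDROPHOBIC
LYS	C	NEUTRAL
LYS	O	H_ACCEPTOR
LYS	OXT	NEGATIVE,H_ACCEPTOR
LYS	CB	HYDROPHOBIC
LYS	CD	HYDROPHOBIC
LYS	CE	HYDROPHOBIC
LYS	CG	HYDROPHOBIC
LYS	NZ	POSITIVE,H_DONOR
MET	N	H_DONOR
MET	CA	HYDROPHOBIC
MET	C	NEUTRAL
MET	O	H_ACCEPTOR
MET	OXT	NEGATIVE,H_ACCEPTOR
MET	CB	HYDROPHOBIC
MET	CE	HYDROPHOBIC
MET	CG	HYDROPHOBIC
MET	SD	SULFUR
MSE	N	H_DONOR
MSE	CA	HYDROPHOBIC
MSE	C	NEUTRAL
MSE	O	H_ACCEPTOR
MSE	OXT	NEGATIVE,H_ACCEPTOR
MSE	CB	HYDROPHOBIC
MSE	CE	HYDROPHOBIC
MSE	CG	HYDROPHOBIC
MSE	SE	SULFUR
PHE	N	H_DONOR
PHE	CA	HYDROPHOBIC
PHE	C	NEUTRAL
PHE	O	H_ACCEPTOR
PHE	OXT	NEGATIVE,H_ACCEPTOR
PHE	CB	HYDROPHOBIC
PHE	CD1	AROMATIC,HYDROPHOBIC
PHE	CD2	AROMATIC,HYDROPHOBIC
PHE	CE1	AROMATIC,HYDROPHOBIC
PHE	CE2	AROMATIC,HYDROPHOBIC
PHE	CG	AROMATIC,HYDROPHOBIC
PHE	CZ	AROMATIC,HYDROPHOBIC
PRO	N	NEUTRAL
PRO	CA	HYDROPHOBIC
PRO	C	NEUTRAL
PRO	O	H_ACCEPTOR
PRO	OXT	NEGATIVE,H_ACCEPTOR
PRO	CB	HYDROPHOBIC
PRO	CD	HYDROPHOBIC
PRO	CG	HYDROPHOBIC
SER	N	H_DONOR
SER	CA	HYDROPHOBIC
SER	C	NEUTRAL
SER	O	H_ACCEPTOR
SER	OXT	NEGATIVE,H_ACCEPTOR
SER	CB	HYDROPHOBIC
SER	OG	H_DONOR,H_ACCEPTOR
THR	N	H_DONOR
THR	CA	HYDROPHOBIC
THR	C	NEUTRAL
THR	O	H_ACCEPTOR
THR	OXT	NEGATIVE,H_ACCEPTOR
THR	CB	HYDROPHOBIC
THR	CG2	HYDROPHOBIC
THR	OG1	H_DONOR,H_ACCEPTOR
TRP	N	H_DONOR
TRP	CA	HYDROPHOBIC
TRP	C	NEUTRAL
TRP	O	H_ACCEPTOR
TRP	OXT	NEGATIVE,H_ACCEPTOR
TRP	CB	HYDROPHOBIC
TRP	CD1	AROMATIC,HYDROPHOBIC
TRP	CD2	AROMATIC,HYDROPHOBIC
TRP	CE2	AROMATIC,HYDROPHOBIC
TRP	CE3	AROMATIC,HYDROPHOBIC
TRP	CG	AROMATIC,HYDROPHOBIC
TRP	CH2	AROMATIC,HYDROPHOBIC
TRP	CZ2	AROMATIC,HYDROPHOBIC
TRP	CZ3	AROMATIC,HYDROPHOBIC
TRP	NE1	AROMATIC,H_DONOR
TYR	N	H_DONOR
TYR	CA	HYDROPHOBIC
TYR	C	NEUTRAL
TYR	O	H_ACCEPTOR
TYR	OXT	NEGATIVE,H_ACCEPTOR
TYR	CB	HYDROPHOBIC
TYR	CD1	AROMATIC,HYDROPHOBIC
TYR	CD2	AROMATIC,HYDROPHOBIC
TYR	CE1	AROMATIC,HYDROPHOBIC
TYR	CE2	AROMATIC,HYDROPHOBIC
TYR	CG	AROMATIC,HYDROPHOBIC
TYR	CZ	AROMATIC,HYDROPHOBIC
TYR	OH	H_DONOR,H_ACCEPTOR
VAL	N	H_DONOR
VAL	CA	HYDROPHOBIC
VAL	C	NEUTRAL
VAL	O	H_ACCEPTOR
VAL	OXT	NEGATIVE,H_ACCEPTOR
VAL	CB	HYDROPHOBIC
VAL	CG1	HYDROPHOBIC
VAL	CG2	HYDROPHOBIC
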