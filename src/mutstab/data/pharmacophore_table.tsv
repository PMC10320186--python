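# res_name	atom_name	labels (semicolon-joined)
ALA	N	HDonor
ALA	CA	Hydrophobic
ALA	C	Neutral
ALA	O	HAcceptor
ALA	CB	Hydrophobic
ALA	OXT	HAcceptor;Negative
ARG	N	HDonor
ARG	CA	Hydrophobic
ARG	C	Neutral
ARG	O	HAcceptor
ARG	CB	Hydrophobic
ARG	CG	Hydrophobic
ARG	CD	Hydrophobic
ARG	NE	HDonor;Positive
ARG	CZ	Neutral
ARG	NH1	HDonor;Positive
ARG	NH2	HDonor;Positive
ARG	OXT	HAcceptor;Negative
ASN	N	HDonor
ASN	CA	Hydrophobic
ASN	C	Neutral
ASN	O	HAcceptor
ASN	CB	Hydrophobic
ASN	CG	Neutral
ASN	OD1	HAcceptor
ASN	ND2	HDonor
ASN	OXT	HAcceptor;Negative
ASP	N	HDonor
ASP	CA	Hydrophobic
ASP	C	Neutral
ASP	O	HAcceptor
ASP	CB	Hydrophobic
ASP	CG	Neutral
ASP	OD1	HAcceptor;Negative
ASP	OD2	HAcceptor;Negative
ASP	OXT	HAcceptor;Negative
CYS	N	HDonor
CYS	CA	Hydrophobic
CYS	C	Neutral
CYS	O	HAcceptor
CYS	CB	Hydrophobic
CYS	SG	HDonor;Sulphur
CYS	OXT	HAcceptor;Negative
GLN	N	HDonor
GLN	CA	Hydrophobic
GLN	C	Neutral
GLN	O	HAcceptor
GLN	CB	Hydrophobic
GLN	CG	Hydrophobic
GLN	CD	Neutral
GLN	OE1	HAcceptor
GLN	NE2	HDonor
GLN	OXT	HAcceptor;Negative
GLU	N	HDonor
GLU	CA	Hydrophobic
GLU	C	Neutral
GLU	O	HAcceptor
GLU	CB	Hydrophobic
GLU	CG	Hydrophobic
GLU	CD	Neutral
GLU	OE1	HAcceptor;Negative
GLU	OE2	HAcceptor;Negative
GLU	OXT	HAcceptor;Negative
GLY	N	HDonor
GLY	CA	Hydrophobic
GLY	C	Neutral
GLY	O	HAcceptor
GLY	OXT	HAcceptor;Negative
HIS	N	HDonor
HIS	CA	Hydrophobic
HIS	C	Neutral
HIS	O	HAcceptor
HIS	CB	Hydrophobic
HIS	CG	Aromatic
HIS	ND1	Aromatic;HDonor;Positive
HIS	CD2	Aromatic
HIS	CE1	Aromatic
HIS	NE2	Aromatic;HDonor;Positive
HIS	OXT	HAcceptor;Negative
ILE	N	HDonor
ILE	CA	Hydrophobic
ILE	C	Neutral
ILE	O	HAcceptor
ILE	CB	Hydrophobic
ILE	CG1	Hydrophobic
ILE	CG2	Hydrophobic
ILE	CD1	Hydrophobic
ILE	OXT	HAcceptor;Negative
LEU	N	HDonor
LEU	CA	Hydrophobic
LEU	C	Neutral
LEU	O	HAcceptor
LEU	CB	Hydrophobic
LEU	CG	Hydrophobic
LEU	CD1	Hydrophobic
LEU	CD2	Hydrophobic
LEU	OXT	HAcceptor;Negative
LYS	N	HDonor
LYS	CA	Hydrophobic
LYS	C	Neutral
LYS	O	HAcceptor
LYS	CB	Hydrophobic
LYS	CG	Hydrophobic
LYS	CD	Hydrophobic
LYS	CE	Hydrophobic
LYS	NZ	HDonor;Positive
LYS	OXT	HAcceptor;Negative
MET	N	HDonor
MET	CA	Hydrophobic
MET	C	Neutral
MET	O	HAcceptor
MET	CB	Hydrophobic
MET	CG	Hydrophobic
MET	SD	Sulphur
MET	CE	Hydrophobic
MET	OXT	HAcceptor;Negative
PHE	N	HDonor
PHE	CA	Hydrophobic
PHE	C	Neutral
PHE	O	HAcceptor
PHE	CB	Hydrophobic
PHE	CG	Aromatic;Hydrophobic
PHE	CD1	Aromatic;Hydrophobic
PHE	CD2	Aromatic;Hydrophobic
PHE	CE1	Aromatic;Hydrophobic
PHE	CE2	Aromatic;Hydrophobic
PHE	CZ	Aromatic;Hydrophobic
PHE	OXT	HAcceptor;Negative
PRO	N	Neutral
PRO	CA	Hydrophobic
PRO	C	Neutral
PRO	O	HAcceptor
PRO	CB	Hydrophobic
PRO	CG	Hydrophobic
PRO	CD	Hydrophobic
PRO	OXT	HAcceptor;Negative
SER	N	HDonor
SER	CA	Hydrophobic
SER	C	Neutral
SER	O	HAcceptor
SER	CB	Hydrophobic
SER	OG	HAcceptor;HDonor
SER	OXT	HAcceptor;Negative
THR	N	HDonor
THR	CA	Hydrophobic
THR	C	Neutral
THR	O	HAcceptor
THR	CB	Hydrophobic
THR	OG1	HAcceptor;HDonor
THR	CG2	Hydrophobic
THR	OXT	HAcceptor;Negative
TRP	N	HDonor
TRP	CA	Hydrophobic
TRP	C	Neutral
TRP	O	HAcceptor
TRP	CB	Hydrophobic
TRP	CG	Aromatic;Hydrophobic
TRP	CD1	Aromatic;Hydrophobic
TRP	CD2	Aromatic;Hydrophobic
TRP	NE1	Aromatic;HDonor
TRP	CE2	Aromatic;Hydrophobic
TRP	CE3	Aromatic;Hydrophobic
TRP	CZ2	Aromatic;Hydrophobic
TRP	CZ3	Aromatic;Hydrophobic
TRP	CH2	Aromatic;Hydrophobic
TRP	OXT	HAcceptor;Negative
TYR	N	HDonor
TYR	CA	Hydrophobic
TYR	C	Neutral
TYR	O	HAcceptor
TYR	CB	Hydrophobic
TYR	CG	Aromatic;Hydrophobic
TYR	CD1	Aromatic;Hydrophobic
TYR	CD2	Aromatic;Hydrophobic
TYR	CE1	Aromatic;Hydrophobic
TYR	CE2	Aromatic;Hydrophobic
TYR	CZ	Aromatic;Hydrophobic
TYR	OH	HAcceptor;HDonor
TYR	OXT	HAcceptor;Negative
VAL	N	HDonor
VAL	CA	Hydrophobic
VAL	C	Neutral
VAL	O	HAcceptor
VAL	CB	Hydrophobic
VAL	CG1	Hydrophobic
VAL	CG2	Hydrophobic
VAL	OXT	HAcceptor;Negative
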