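# Gene-name synonym table: raw name (upper-cased, stripped) -> canonical symbol
# Covers common GenBank / MITOS dialects for the 37 mitochondrial genes + CR.
COX1	cox1
COI	cox1
CO1	cox1
COXI	cox1
CYTOCHROME C OXIDASE SUBUNIT 1	cox1
CYTOCHROME C OXIDASE SUBUNIT I	cox1
COX2	cox2
COII	cox2
CO2	cox2
COXII	cox2
CYTOCHROME C OXIDASE SUBUNIT 2	cox2
CYTOCHROME C OXIDASE SUBUNIT II	cox2
COX3	cox3
COIII	cox3
CO3	cox3
COXIII	cox3
CYTOCHROME C OXIDASE SUBUNIT 3	cox3
CYTOCHROME C OXIDASE SUBUNIT III	cox3
COB	cob
CYTB	cob
CYB	cob
CYTOCHROME B	cob
ND1	nad1
NAD1	nad1
NADH1	nad1
NADH DEHYDROGENASE SUBUNIT 1	nad1
ND2	nad2
NAD2	nad2
NADH DEHYDROGENASE SUBUNIT 2	nad2
ND3	nad3
NAD3	nad3
NADH DEHYDROGENASE SUBUNIT 3	nad3
ND4	nad4
NAD4	nad4
NADH DEHYDROGENASE SUBUNIT 4	nad4
ND4L	nad4L
NAD4L	nad4L
NADH DEHYDROGENASE SUBUNIT 4L	nad4L
ND5	nad5
NAD5	nad5
NADH DEHYDROGENASE SUBUNIT 5	nad5
ND6	nad6
NAD6	nad6
NADH DEHYDROGENASE SUBUNIT 6	nad6
ATP6	atp6
ATPASE6	atp6
ATP SYNTHASE F0 SUBUNIT 6	atp6
ATP8	atp8
ATPASE8	atp8
ATP SYNTHASE F0 SUBUNIT 8	atp8
RRNL	rrnL
16S	rrnL
16S RIBOSOMAL RNA	rrnL
L-RRNA	rrnL
LARGE SUBUNIT RIBOSOMAL RNA	rrnL
RRNS	rrnS
12S	rrnS
12S RIBOSOMAL RNA	rrnS
S-RRNA	rrnS
SMALL SUBUNIT RIBOSOMAL RNA	rrnS
TRNA	trnA
TRNA-ALA	trnA
TRNR	trnR
TRNA-ARG	trnR
TRNN	trnN
TRNA-ASN	trnN
TRND	trnD
TRNA-ASP	trnD
TRNC	trnC
TRNA-CYS	trnC
TRNE	trnE
TRNA-GLU	trnE
TRNQ	trnQ
TRNA-GLN	trnQ
TRNG	trnG
TRNA-GLY	trnG
TRNH	trnH
TRNA-HIS	trnH
TRNI	trnI
TRNA-ILE	trnI
TRNK	trnK
TRNA-LYS	trnK
TRNM	trnM
TRNA-MET	trnM
TRNF	trnF
TRNA-PHE	trnF
TRNP	trnP
TRNA-PRO	trnP
TRNT	trnT
TRNA-THR	trnT
TRNW	trnW
TRNA-TRP	trnW
TRNV	trnV
TRNA-VAL	trnV
TRNY	trnY
TRNA-TYR	trnY
TRNL1	trnL1
TRNA-LEU1	trnL1
TRNL2	trnL2
TRNA-LEU2	trnL2
TRNS1	trnS1
TRNA-SER1	trnS1
TRNS2	trnS2
TRNA-SER2	trnS2
CR	CR
D-LOOP	CR
CONTROL REGION	CR
A+T-RICH REGION	CR
AT-RICH REGION	CR
PUTATIVE CONTROL REGION	CR
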