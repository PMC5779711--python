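# Restriction enzyme registry: name<TAB>recognition<TAB>cut_top<TAB>cut_bottom
# Offsets are relative to the recognition-site start on the top strand;
# cut_top < cut_bottom gives a 5' overhang, > gives 3', = gives blunt.
# Geometries are the standard published ones for each enzyme.
EcoRI	GAATTC	1	5
BamHI	GGATCC	1	5
HindIII	AAGCTT	1	5
XhoI	CTCGAG	1	5
SalI	GTCGAC	1	5
NcoI	CCATGG	1	5
NdeI	CATATG	2	4
ClaI	ATCGAT	2	4
SpeI	ACTAGT	1	5
XbaI	TCTAGA	1	5
NheI	GCTAGC	1	5
AvrII	CCTAGG	1	5
BglII	AGATCT	1	5
MfeI	CAATTG	1	5
MluI	ACGCGT	1	5
AflII	CTTAAG	1	5
ApaLI	GTGCAC	1	5
AgeI	ACCGGT	1	5
XmaI	CCCGGG	1	5
PciI	ACATGT	1	5
NotI	GCGGCCGC	2	6
AscI	GGCGCGCC	2	6
EcoRV	GATATC	3	3
SmaI	CCCGGG	3	3
PvuII	CAGCTG	3	3
HpaI	GTTAAC	3	3
ScaI	AGTACT	3	3
StuI	AGGCCT	3	3
DraI	TTTAAA	3	3
SspI	AATATT	3	3
PmeI	GTTTAAAC	4	4
SwaI	ATTTAAAT	4	4
KpnI	GGTACC	5	1
SacI	GAGCTC	5	1
SphI	GCATGC	5	1
PstI	CTGCAG	5	1
ApaI	GGGCCC	5	1
AatII	GACGTC	5	1
NsiI	ATGCAT	5	1
SacII	CCGCGG	4	2
BsaI	GGTCTC	7	11
BsmBI	CGTCTC	7	11
BbsI	GAAGAC	8	12
SapI	GCTCTTC	8	11
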