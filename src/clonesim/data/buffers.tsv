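# Buffer activity table: vendor<TAB>buffer<TAB>alias<TAB>activity(0-100)
# Activity percentages are SYNTHETIC illustrative values shaped like
# vendor double-digest charts; they are not vendor-published numbers.
NEB	rCutSmart	EcoRI-HF	100
NEB	rCutSmart	EcoRI	50
NEB	rCutSmart	BamHI-HF	100
NEB	rCutSmart	BamHI	75
NEB	rCutSmart	HindIII-HF	100
NEB	rCutSmart	HindIII	50
NEB	rCutSmart	SpeI-HF	100
NEB	rCutSmart	SpeI	75
NEB	rCutSmart	NotI-HF	100
NEB	rCutSmart	SalI-HF	100
NEB	rCutSmart	SalI	0
NEB	rCutSmart	XhoI	75
NEB	rCutSmart	NcoI-HF	100
NEB	rCutSmart	PstI	75
NEB	rCutSmart	KpnI-HF	100
NEB	rCutSmart	SacI-HF	100
NEB	rCutSmart	BsaI-HFv2	100
NEB	rCutSmart	EcoRV-HF	100
NEB	rCutSmart	SmaI	100
NEB	r1.1	EcoRI	25
NEB	r1.1	BamHI	50
NEB	r1.1	HindIII	50
NEB	r1.1	SpeI	100
NEB	r1.1	SalI	10
NEB	r1.1	XhoI	75
NEB	r1.1	NcoI	50
NEB	r1.1	PstI	50
NEB	r1.1	KpnI	100
NEB	r1.1	SacI	100
NEB	r1.1	SmaI	50
NEB	r2.1	EcoRI	100
NEB	r2.1	BamHI	100
NEB	r2.1	HindIII	100
NEB	r2.1	SpeI	75
NEB	r2.1	SalI	75
NEB	r2.1	XhoI	100
NEB	r2.1	NcoI	100
NEB	r2.1	PstI	75
NEB	r2.1	KpnI	75
NEB	r2.1	SacI	50
NEB	r2.1	SmaI	25
NEB	r3.1	EcoRI	100
NEB	r3.1	BamHI	100
NEB	r3.1	HindIII	50
NEB	r3.1	SpeI	25
NEB	r3.1	SalI	100
NEB	r3.1	XhoI	100
NEB	r3.1	NcoI	75
NEB	r3.1	PstI	100
NEB	r3.1	KpnI	25
NEB	r3.1	SacI	10
NEB	r3.1	SmaI	10
Thermofisher	B	EcoRI	50
Thermofisher	B	BamHI	100
Thermofisher	B	HindIII	100
Thermofisher	B	BcuI	50
Thermofisher	B	KpnI	100
Thermofisher	B	SacI	100
Thermofisher	G	EcoRI	75
Thermofisher	G	BamHI	100
Thermofisher	G	HindIII	50
Thermofisher	G	BcuI	75
Thermofisher	G	XhoI	50
Thermofisher	G	PstI	100
Thermofisher	O	EcoRI	100
Thermofisher	O	BamHI	75
Thermofisher	O	HindIII	50
Thermofisher	O	BcuI	50
Thermofisher	O	SalI	100
Thermofisher	O	XhoI	100
Thermofisher	O	NcoI	75
Thermofisher	O	PstI	100
Thermofisher	R	EcoRI	100
Thermofisher	R	BamHI	50
Thermofisher	R	HindIII	100
Thermofisher	R	BcuI	25
Thermofisher	R	SalI	75
Thermofisher	R	XhoI	75
Thermofisher	R	NcoI	50
Thermofisher	Tango	EcoRI	100
Thermofisher	Tango	BamHI	75
Thermofisher	Tango	HindIII	100
Thermofisher	Tango	BcuI	100
Thermofisher	Tango	SalI	50
Thermofisher	Tango	XhoI	75
Thermofisher	Tango	NcoI	75
Thermofisher	Tango	KpnI	75
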