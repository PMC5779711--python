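# Vendor alias table: alias<TAB>canonical<TAB>vendor
# A vendor product name (including HF variants and isoschizomer trade
# names) maps to exactly one canonical enzyme.
EcoRI	EcoRI	NEB
EcoRI-HF	EcoRI	NEB
BamHI	BamHI	NEB
BamHI-HF	BamHI	NEB
HindIII	HindIII	NEB
HindIII-HF	HindIII	NEB
SpeI	SpeI	NEB
SpeI-HF	SpeI	NEB
NotI	NotI	NEB
NotI-HF	NotI	NEB
SalI	SalI	NEB
SalI-HF	SalI	NEB
XhoI	XhoI	NEB
NcoI	NcoI	NEB
NcoI-HF	NcoI	NEB
PstI	PstI	NEB
KpnI	KpnI	NEB
KpnI-HF	KpnI	NEB
SacI	SacI	NEB
SacI-HF	SacI	NEB
BsaI	BsaI	NEB
BsaI-HFv2	BsaI	NEB
EcoRV	EcoRV	NEB
EcoRV-HF	EcoRV	NEB
SmaI	SmaI	NEB
EcoRI	EcoRI	Thermofisher
BamHI	BamHI	Thermofisher
HindIII	HindIII	Thermofisher
BcuI	SpeI	Thermofisher
NotI	NotI	Thermofisher
SalI	SalI	Thermofisher
XhoI	XhoI	Thermofisher
NcoI	NcoI	Thermofisher
PstI	PstI	Thermofisher
KpnI	KpnI	Thermofisher
SacI	SacI	Thermofisher
Eco32I	EcoRV	Thermofisher
Eco88I	XmaI	Thermofisher
BveI	BbsI	Thermofisher
Eco31I	BsaI	Thermofisher
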