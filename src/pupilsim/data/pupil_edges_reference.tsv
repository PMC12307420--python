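source	target	sign
R	PTA	+
PTA	EWpg	+
EWpg	CG	+
CG	plant.sphincter	+
AMY	LH	+
LH	DMH	+
DMH	PVN	+
DMH	IML	+
PVN	IML	+
IML	SCG	+
SCG	plant.dilator	+
R	SCN	+
SCN	VLPO	+
VLPO	LC	-
AMY	LC	+
LC	EWpg	shunt
R	LGN	+
LGN	Cortex	+
R	SC	+
SC	PULV	+
PULV	AMY	+
Cortex	CB	+
Cortex.surprise	AMY.surprise	+
CB	EWpg	+
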