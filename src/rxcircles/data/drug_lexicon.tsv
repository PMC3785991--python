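# Prescription-drug keyword lexicon: category<TAB>keyword, one per line.
# A trailing "*" on a keyword matches 0 or more additional characters.
Adderall	adderall
Xanax	xanax
Klonopin	klonopin
Valium	valium
Valium	sleeping pills
Painkillers	painkiller*
Painkillers	pain killer*
Painkillers	narcotic painkiller*
Painkillers	oxycontin
Painkillers	vicodin
Painkillers	percodan
Painkillers	percocet
Painkillers	darvon
Painkillers	lortab
Painkillers	lorcet
Painkillers	dilaudid
Painkillers	demerol
Painkillers	lomotil
Painkillers	kadian
Painkillers	avinza
Painkillers	codeine
Painkillers	duragesic
Painkillers	methadone
Depressants	mebaral
Depressants	nembutal
Depressants	sodium pentobarbital
Depressants	halcion
Depressants	prosam
Depressants	ativan
Depressants	librium
Depressants	depressant*
Stimulants	dexedrine
Stimulants	ritalin
Stimulants	concerta
Stimulants	amphetamines
Stimulants	stimulant*
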