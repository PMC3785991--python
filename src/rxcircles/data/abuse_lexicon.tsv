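# Risk/abusive-behavior keyword lexicon: category<TAB>keyword, one per line.
# A trailing "*" on a keyword matches 0 or more additional characters.
# Duplicated keywords inside a category are transcribed as printed; the loader
# dedupes them with no semantic effect.
# Restrictions (enforced in code, not here):
#   - co-ingestion "xanax" is inert for Xanax-category posts; "adderall" for Adderall
#   - "test", "final", "study", "studying" fire only for Adderall-category posts
#   - "skinny" fires only for Stimulants-category posts
larger_doses_overdose	too many
larger_doses_overdose	two
larger_doses_overdose	three
larger_doses_overdose	double
larger_doses_overdose	too much
larger_doses_overdose	overdose
larger_doses_overdose	crash
larger_doses_overdose	strong enough
larger_doses_overdose	max
larger_doses_overdose	too many
co_ingestion	alcohol
co_ingestion	coffee
co_ingestion	white
co_ingestion	red
co_ingestion	wine
co_ingestion	vodka
co_ingestion	shots
co_ingestion	patron
co_ingestion	booze
co_ingestion	margarita
co_ingestion	mimosa
co_ingestion	xanax
co_ingestion	painkiller
co_ingestion	caffeine
co_ingestion	alcohol
co_ingestion	happy pills
co_ingestion	adderall
co_ingestion	concerta
co_ingestion	cocaine
co_ingestion	rum
more_frequent_doses	enough
more_frequent_doses	pop
more_frequent_doses	popping
more_frequent_doses	not enough
more_frequent_doses	another
more_frequent_doses	enough
more_frequent_doses	pop*
alternative_motives_dependence	test
alternative_motives_dependence	final
alternative_motives_dependence	study
alternative_motives_dependence	studying
alternative_motives_dependence	problems
alternative_motives_dependence	college
alternative_motives_dependence	class
alternative_motives_dependence	breakfast
alternative_motives_dependence	rely
alternative_motives_dependence	sleep
alternative_motives_dependence	sleeping
alternative_motives_dependence	work
alternative_motives_dependence	family problems
alternative_motives_dependence	sleep*
alternative_motives_dependence	stress*
alternative_motives_dependence	stressful
alternative_motives_dependence	stress
alternative_motives_dependence	skinny
alternative_routes	snort
alternative_routes	crush
alternative_routes	inject
alternative_routes	snort
alternative_routes	inhale
legitimacy_of_obtaining	steal*
trading_selling	buy
trading_selling	sell
trading_selling	trade
trading_selling	share
trading_selling	spend
trading_selling	buy
trading_selling	bring
seeking	need
seeking	want
seeking	needing
seeking	wanting
seeking	wish
seeking	need
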