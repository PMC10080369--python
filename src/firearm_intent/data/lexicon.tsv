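surface	category	tags
shot	shooting_verb	-
fired	shooting_verb	-
discharged	shooting_verb	-
gsw	firearm_term	-
gunshot	firearm_term	-
gunshot wound	firearm_term	-
gun	firearm_term	-
handgun	firearm_term	-
firearm	firearm_term	-
bullet	firearm_term	-
shooting	firearm_term	-
at home	incident_location	location=inside
nightclub	incident_location	location=inside
in the street	incident_location	location=outside
parking lot	incident_location	location=outside
accidental discharge	explicit_intent_accident	-
accidentally discharged	explicit_intent_accident	-
accidentally shot	explicit_intent_accident	-
unintentional	explicit_intent_accident	-
altercation	explicit_intent_assault	-
robbery	explicit_intent_assault	-
assailant	explicit_intent_assault	-
drive by	explicit_intent_assault	-
suicide attempt	explicit_intent_self_harm	-
si	explicit_intent_self_harm	-
suicidal ideation	explicit_intent_self_harm	-
self inflicted	explicit_intent_self_harm	-
officer involved shooting	explicit_intent_legal	-
police	police_actor	-
officer	police_actor	-
officers	police_actor	-
law enforcement	police_actor	-
swat	police_actor	-
police report	confusion_term	-
police station	confusion_term	-
circumstances of shooting unknown	no_info_attestation	-
intent unclear	no_info_attestation	-
unknown intent	no_info_attestation	-
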