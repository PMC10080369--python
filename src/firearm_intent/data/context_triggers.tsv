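surface	category	tags
denies	negation_trigger	-
denied	negation_trigger	-
no	negation_trigger	-
not	negation_trigger	-
negative for	negation_trigger	-
without	negation_trigger	-
history of	history_trigger	-
h/o	history_trigger	-
hx of	history_trigger	-
years ago	history_trigger	-
prior	history_trigger	-
old	history_trigger	-
brother	other_subject_trigger	-
sister	other_subject_trigger	-
friend	other_subject_trigger	-
family member	other_subject_trigger	-
cousin	other_subject_trigger	-
father	other_subject_trigger	-
mother	other_subject_trigger	-
but	scope_terminator	-
however	scope_terminator	-
;	scope_terminator	-
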