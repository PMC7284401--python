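# Greeting templates, one per line. A line is excluded as greeting-only when
# every non-stop-word token belongs to the vocabulary built from these templates.
thank you
thanks
thank you so much
many thanks
hello
hi
hey
good morning
good afternoon
good evening
ok
okay
great
got it
you're welcome
best
regards
take care
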