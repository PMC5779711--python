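# gRNA registry: name<TAB>spacer<TAB>pam<TAB>cut_offset
# cut_offset: blunt cut this many bp 5' (PAM-proximal) of the
# protospacer 3' end; SpCas9 cuts 3 bp from the PAM.
# The spacer below is an arbitrary demonstration target.
demo-SpCas9	GGTCAGGTTCAACGGATCCA	NGG	3
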