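>TCP_domain_classI synthetic 55-aa Class I (PCF-style) reference lacking four basic-region residues
KRKDRHSAQGPRDRRMRLSLDVARKFFDLQDMLGFDKASKTLDWLLTKSKTAIQE
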