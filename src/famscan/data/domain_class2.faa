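>TCP_domain_classII synthetic 59-aa Class II (CIN/CYC-style) basic-helix-loop-helix reference
KRKDRHSKINTAQGPRDRRMRLSLDVARKFFDLQDMLGFDKASKTLDWLLTKSKTAIQE
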