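hairpin{stem 4..8; loop 9..12 motif CCUCCUCCC} x3
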