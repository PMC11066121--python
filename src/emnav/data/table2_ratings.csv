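investigator,usefulness,realistic_implementation,accuracy_level
1,5,3,4
2,5,4,5
3,4,3,4
4,5,5,5
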