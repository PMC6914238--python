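# Published fielding flow of the 2018 Q3 survey wave.
invited: 148274
initiated: 40021
eligible_complete: 29998
excluded: 157
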