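age_years,sex,lower,upper
3,Boys,14.1,17.7
3,Girls,13.9,17.6
4,Boys,13.9,17.6
4,Girls,13.7,17.4
5,Boys,13.7,17.4
5,Girls,13.5,17.2
6,Boys,13.6,17.6
6,Girls,13.4,17.3
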