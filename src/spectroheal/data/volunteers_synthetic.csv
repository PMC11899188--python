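Volunteer,Sex,Age (years)
V1,F,26
V2,M,39
V3,F,43
V4,M,43
V5,F,45
V6,M,46
V7,F,47
V8,M,49
V9,F,51
V10,M,52
V11,F,54
V12,M,55
V13,F,57
V14,M,58
V15,F,60
V16,M,61
V17,F,62
V18,M,63
V19,F,64
V20,M,65
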