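model,R,R2,Q2
Original,0.94,0.88,0.81
Random 1,0.55,0.30,-0.20
Random 2,0.11,0.01,-0.91
Random 3,0.44,0.19,-0.51
Random 4,0.23,0.05,-0.74
Random 5,0.38,0.14,-0.54
Random 6,0.39,0.15,-0.54
Random 7,0.50,0.25,-0.49
Random 8,0.57,0.32,-0.34
Random 9,0.33,0.11,-0.73
Random 10,0.23,0.05,-0.65
Random 11,0.28,0.08,-0.65
Random 12,0.29,0.09,-0.59
Random 13,0.47,0.22,-0.41
Random 14,0.50,0.25,-0.40
Random 15,0.54,0.29,-0.11
Random 16,0.28,0.08,-0.62
Random 17,0.32,0.10,-0.48
Random 18,0.34,0.12,-0.51
Random 19,0.35,0.13,-0.48
Random 20,0.39,0.15,-0.63
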