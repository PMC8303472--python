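id,white_pixels,planimetry_cm2,normalized_mean
Patient 1,325,1.12,166
Patient 2,722,1.44,174
Patient 3,242,0.81,168
Patient 4,669,1.96,170
Patient 5,2251,2.67,175
Patient 6,2565,2.82,190
Patient 7,1026,1.98,188
Patient 8,917,1.45,174
Patient 9,1007,1.62,178
Patient 10,1315,1.77,172
Patient 11,206,0.72,165
Patient 12,1771,1.99,186
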