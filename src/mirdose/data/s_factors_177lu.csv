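organ,s_gy_per_bq_s,mass_g
Heart,4.66E-11,0.141
Lungs,3.78E-11,0.208
Liver,1.47E-11,1.333
Kidneys,3.95E-11,0.362
Spleen,1.62E-10,0.118
Brain,5.21E-11,0.388
Tumors,1.32E-09,0.016
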