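organ,tracer,dose_gy_per_MBq,sd_gy_per_MBq
Heart,Tz-1,1.87E-03,8.74E-04
Heart,Tz-2,2.19E-03,7.61E-04
Heart,Tz-3,1.00E-03,3.29E-04
Heart,Tz-4,3.41E-03,5.38E-04
Lungs,Tz-1,4.37E-03,9.67E-04
Lungs,Tz-2,3.87E-03,1.19E-03
Lungs,Tz-3,2.31E-03,2.75E-03
Lungs,Tz-4,6.41E-03,1.32E-03
Liver,Tz-1,7.56E-02,1.89E-02
Liver,Tz-2,1.60E-02,4.76E-03
Liver,Tz-3,1.05E-03,3.50E-04
Liver,Tz-4,2.06E-02,1.36E-03
Kidneys,Tz-1,2.59E-02,2.52E-03
Kidneys,Tz-2,2.59E-02,2.55E-03
Kidneys,Tz-3,6.62E-03,3.29E-03
Kidneys,Tz-4,2.70E-02,8.25E-04
Spleen,Tz-1,2.30E-02,7.34E-03
Spleen,Tz-2,2.06E-01,2.06E-02
Spleen,Tz-3,2.14E-02,1.56E-02
Spleen,Tz-4,2.56E-02,9.75E-03
Brain,Tz-1,1.16E-03,9.12E-04
Brain,Tz-2,7.95E-04,3.38E-04
Brain,Tz-3,8.63E-04,1.10E-03
Brain,Tz-4,1.13E-03,4.30E-04
Tumors,Tz-1,2.53E-01,1.56E-01
Tumors,Tz-2,5.92E-01,5.22E-01
Tumors,Tz-3,1.83E-01,1.13E-01
Tumors,Tz-4,6.31E-01,5.59E-01
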