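# Degree-based descriptor values for 13 cancer drugs, transcribed from the
# published table. Ambiguous cells in the source rendering were resolved by
# recomputation from the drug structures (see docs/methods.md).
drug,AZI,M1,M2,mM2,H,ReZG3,SDD,I,F
Abemaciclib,98.1406,58,63,3.1111,6,298,30,13.6667,140
Abraxane,592.718,361,458,13.1181,28.2357,2580,165.333,84.5976,1023
Anastrozole,139.701,94,108,3.6944,7.819,558,47.8333,21.3643,258
Capecitabine,213.219,128,149,6,11.8333,760,63.3333,30.0833,330
Cyclophosphamide,112.1946,64,72,3.4167,6.4857,368,32.6667,14.9143,166
Exemestane,240.867,156,208,4.9861,10.5714,1308,74.75,34.8452,500
Fulvestrant,340.536,212,251,8.6181,18.0548,1346,105,48.8952,584
Ixabepilone,273.146,186,220,7.4444,15.1571,1188,95,42.0095,524
Letrozole,202.1721,112,131,5.0833,10.6333,646,51,27.2333,276
Megestrol Acetate,253.422,164,209,5.8125,12.2262,1218,78.1667,37.3905,488
Methotrexate,279.359,172,200,7.6111,15.5,1014,84.3333,40.4167,444
Tamoxifen,244.313,138,158,6.4444,13.4,768,65,33.3667,336
Thiotepa,115.842,68,88,2.25,5.1571,500,29.5,16.1429,194
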