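# Physicochemical properties of 13 cancer drugs, transcribed from the
# published table. BP boiling point (C), EoV enthalpy of vaporization
# (kJ/mol), FP flash point (C), MR molar refractivity (cm^3), MV molar
# volume (cm^3), P polarizability (A^3), MW molecular weight (g/mol),
# MM monoisotopic mass (g/mol), PSA topological polar surface area (A^2),
# HAC heavy atom count, C complexity.
drug,BP,EoV,FP,MR,MV,P,MW,MM,PSA,HAC,C
Abemaciclib,689.3,101,370.7,140.4,382.3,55.7,506.6,506.27,75,37,738
Abraxane,957.1,146,532.6,219.3,610.6,86.9,853.9,853.3,221,62,1790
Anastrozole,469.7,73.2,237.9,90,270.3,35.7,293.4,293.16,78.3,22,456
Capecitabine,517.0,81.2,87,82.3,240.5,32.6,359.4,359.1,121,25,582
Cyclophosphamide,336.1,57.9,157.1,58.1,195.7,23,261.1,260.02,41.6,14,212
Exemestane,453.7,71.3,169,85.8,260.6,34,296.4,296.17,34.1,22,653
Fulvestrant,674.8,104.1,361.9,154,505.1,61.1,606.8,606.31,76.7,41,854
Ixabepilone,697.8,107.3,375.8,140.1,451.6,55.5,506.7,506.2,140,35,817
Letrozole,563.5,84.7,294.6,87.1,234.5,34.5,285.3,285.1,78.3,22,420
Megestrol Acetate,507.1,77.7,77.7,106.4,333.4,42.2,384.5,384.23,60.4,28,821
Methotrexate,561.3,84.1,284.15,119,295.7,47.2,454.4,454.17,211,33,704
Tamoxifen,482.3,74.7,140,118.9,118.9,47.1,371.5,371.2,12.5,28,463
Thiotepa,270.2,50.8,117.2,49.1,125.8,19.5,189.2,189.04,41.1,11,194
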