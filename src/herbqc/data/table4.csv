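id,rt_min,adduct,measured_mz,calc_mz,ppm,formula,name
P1,1.4,[M+H]+,144.1015,144.1019,-2.78,C7H13NO2,stachydrine
P2,30.8,[M-H]-,301.0727,301.0718,2.99,C16H14O6,carasinaurone
P3,31.58,[M+H]+,447.1281,447.1286,-1.12,C22H22O10,calycosin-7-O-b-d-glucoside
P4,65.48,[M+FA-H]-,781.4405,781.4380,3.20,C40H64O12,akebia saponin B
M1,25.78,[M-H]-,509.0412,509.0395,3.34,C21H18O13S,daidzein + sulfation + glucuronidation
M2,27.92,[M-H]-,621.1487,621.1461,4.19,C28H30O16,calycosin-7-O-b-d-glucoside + glucuronidation
M3,28.14,[M-H]-,509.0415,509.0395,3.93,C21H18O13S,daidzein + sulfation + glucuronidation
M4,28.81,[M-H]-,429.0836,429.0827,2.10,C21H18O10,daidzein + glucuronidation
M5,28.81,[M-H]-,525.0359,525.0345,2.67,C21H18O14S,apigenin + sulfation + glucuronidation
M6,29.71,[M-H]-,459.0946,459.0933,2.83,C22H20O11,genkwanin + glucuronidation
M7,30.75,[M-H]-,497.0775,497.0759,3.22,C21H22O12S,equol + sulfation + glucuronidation
M8,31.56,[M-H]-,429.0843,429.0827,3.73,C21H18O10,daidzein + glucuronidation
M9,31.75,[M-H]-,541.0301,541.0294,1.29,C21H18O15S,apigenin + hydroxylation + glucuronidation + sulfation
M10,32.96,[M-H]-,445.0794,445.0776,4.04,C21H18O11,apigenin + glucuronidation
M11,33.69,[M-H]-,433.1158,433.114,4.16,C21H22O10,trihydroxyisoflavan + glucuronidation
M12,33.65,[M-H]-,491.1575,491.1559,3.26,C24H28O11,hydroxy-trimethoxyisoflavan + glucuronidation
M13,34.78,[M-H]-,445.0798,445.0776,4.94,C21H18O11,apigenin + glucuronidation
M14,34.84,[M-H]-,333.0089,333.0074,4.50,C15H10O7S,daidzein + sulfation
M15,34.88,[M-H]-,447.0940,447.0933,1.57,C21H20O11,trihydroxyisoflavanone + glucuronidation
M16,35.55,[M-H]-,459.0950,459.0933,3.70,C22H20O11,calycosin + glucuronidation
M17,35.55,[M-H]-,417.1207,417.1191,3.84,C21H22O9,equol + glucuronidation
M18,35.91,[M-H]-,447.0943,447.0933,2.24,C21H20O11,trihydroxyisoflavanone + glucuronidation
M19,36.18,[M-H]-,417.1210,417.1191,4.56,C21H22O9,equol + glucuronidation
M20,36.11,[M-H]-,639.1957,639.1931,4.07,C29H36O16,astraisoflavan-7-O-b-d-glucoside + glucuronidation
M21,38.58,[M-H]-,417.1207,417.1191,3.84,C21H22O9,equol + glucuronidation
M22,38.63,[M-H]-,321.0449,321.0438,3.43,C15H14O6S,equol + sulfation
M23,38.92,[M-H]-,443.0999,443.0984,3.39,C22H20O10,formononetin + glucuronidation
M24,40.04,[M-H]-,253.0511,253.0506,1.98,C15H10O4,formononetin + demethylation
M25,40.86,[M-H]-,433.1153,433.114,3.00,C21H22O10,trihydroxyisoflavan + glucuronidation
M26,41.42,[M-H]-,433.1157,433.114,3.93,C21H22O10,trihydroxyisoflavan + glucuronidation
M27,41.99,[M-H]-,475.1267,475.1246,4.42,C23H24O11,methylnissolin + glucuronidation
M28,42.76,[M-H]-,459.0951,459.0933,3.92,C22H20O11,calycosin + glucuronidation
M29,43.13,[M-H]-,477.1421,477.1402,3.98,C23H26O11,astraisoflavan + glucuronidation
M30,43.28,[M+H]+,303.1212,303.1227,-4.95,C17H18O5,astraisoflavan
M31,44.51,[M-H]-,445.1154,445.114,3.15,C22H22O10,formononetin + hydrogenation + glucuronidation
M32,45.68,[M-H]-,347.0230,347.0231,-0.29,C16H12O7S,formononetin + sulfation
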