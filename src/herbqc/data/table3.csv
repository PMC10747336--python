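id,rt_min,adduct,measured_mz,calc_mz,ppm,formula,name
C1,0.99,[M+H]+,118.0858,118.0863,-4.23,C5H11NO2,betaine
C2,1.16,[M+H]+,144.1014,144.1019,-3.47,C7H13NO2,stachydrine
C3,18.55,[M-H]-,431.1208,431.1195,3.02,C18H24O12,asperulosidic acid
C4,18.96,[M-H]-,313.0923,313.0929,-1.92,C14H18O8,glucovanillin
C5,19.49,[M-H]-,353.0890,353.0878,3.40,C16H18O9,neochlorogenic acid
C6,20.56,[M-H]-,593.2094,593.2087,1.18,C25H38O16,leonuriside B
C7,23.06,[M-H]-,353.0884,353.0878,1.70,C16H18O9,chlorogenic acid
C8,23.74,[M-H]-,353.0881,353.0878,0.85,C16H18O9,cryptochlorogenic acid
C9,25.53,[M-H]-,463.1254,463.1246,1.73,C22H24O11,hesperetin 7-O-glucoside
C10,28.62,[M+H]+,312.1540,312.1554,-4.48,C14H21N3O5,leonurine
C11,30.41,[M-H]-,301.0715,301.0718,-1.00,C16H14O6,carasinaurone
C12,30.86,[M+H]+,447.1269,447.1286,-3.80,C22H22O10,calycosin-7-O-b-d-glucoside
C13,33.14,[M-H]-,477.1419,477.1402,3.56,C23H26O11,calceolarioside B
C14,34.08,[M-H]-,515.1211,515.1195,3.11,C25H24O12,isochlorogenic acid B
C15,34.81,[M-H]-,515.1212,515.1195,3.30,C25H24O12,isochlorogenic acid A
C16,35.70,[M-H]-,461.1461,461.1453,1.73,C23H26O10,methylnissolin-3-O-glucoside
C17,36.68,[M-H]-,515.1202,515.1195,1.36,C25H24O12,isochlorogenic acid C
C18,38.03,[M+FA-H]-,475.1247,475.1246,0.21,C22H22O9,ononin
C19,39.17,[M+H]+,1075.5305,1075.532,-1.21,C52H82O23,mutongsaponin B
C20,40.41,[M+FA-H]-,987.4837,987.4806,3.14,C47H74O19,saponin Ph
C21,42.03,[M-H]-,283.0617,283.0612,1.77,C16H12O5,genkwanin
C22,42.08,[M-H]-,463.1608,463.161,-0.43,C23H28O10,astraisoflavan-7-O-b-d-glucoside
C23,42.61,[M+FA-H]-,1003.5116,1003.5119,-0.30,C48H78O19,scheffoleoside A
C24,42.79,[M+H]+,1091.5630,1091.5633,-0.27,C53H86O23,akebia saponin
C25,43.60,[M-H]-,431.1001,431.0984,3.94,C21H20O10,apigenin 7-O-glucoside
C26,43.96,[M+FA-H]-,1003.5109,1003.5119,-1.00,C48H78O19,asiaticoside
C27,44.10,[M+H]+,1091.5579,1091.5633,-4.95,C53H86O23,23-hydroxyakemisaponin A
C28,44.73,[M+FA-H]-,1003.5154,1003.5119,3.49,C48H78O19,trihydroxy-olean-12-en-28-oic acid triglycoside ester
C29,45.53,[M+FA-H]-,969.2802,969.2764,3.92,C56H44O13,kobophenol A
C30,49.65,[M+FA-H]-,1105.5449,1105.5436,1.18,C52H84O22,akebia saponin E
C31,50.55,[M+FA-H]-,973.5012,973.5014,-0.21,C47H76O18,akebia saponin D
C32,51.88,[M-H]-,267.0656,267.0663,-2.62,C16H12O4,formononetin
C33,55.19,[M+Cl]-,933.4640,933.4620,2.14,C46H74O17,23-hydroxy-olean-12-en-28-oic acid arabinosyl-glucosyl-arabinoside
C34,56.36,[M+FA-H]-,1089.5523,1089.5487,3.30,C52H84O21,yuzhizioside IV
C35,59.25,[M+FA-H]-,871.4718,871.4697,2.41,C43H70O15,astragaloside II
C36,61.63,[M+FA-H]-,871.4689,871.4697,-0.92,C43H70O15,astrasieversianin VII
C37,63.61,[M+FA-H]-,871.4731,871.4697,3.90,C43H70O15,cyclosiversioside D
C38,63.95,[M+FA-H]-,957.5079,957.5123,-4.60,C47H76O17,pulsatilla saponin D
C39,64.27,[M-H]-,487.3428,487.3429,-0.21,C30H48O5,arjunolic acid
C40,64.84,[M+FA-H]-,781.4380,781.4380,0.00,C40H64O12,akebia saponin B
C41,65.12,[M+FA-H]-,913.4847,913.4802,4.93,C45H72O16,astragaloside I
C42,65.53,[M-H]-,269.0457,269.0455,0.74,C15H10O5,apigenin
C43,65.71,[M+FA-H]-,913.4814,913.4802,1.31,C45H72O16,isoastragaloside I
C44,66.41,[M+FA-H]-,913.4811,913.4802,0.99,C45H72O16,neoastragaloside I
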