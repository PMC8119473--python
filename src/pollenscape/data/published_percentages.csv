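city,severity,AAAAI,AIA,ARL,Citree,EAN,INSPQ,OPALS,Pollen.com,RNSA
Barcelona,high,14,7,4,5,1,7,46,10,13
Barcelona,moderate,32,16,21,17,0,13,39,25,8
Barcelona,low,8,36,14,14,44,12,14,38,46
Barcelona,not_reported,46,42,62,65,55,68,1,27,33
Montreal,high,50,1,4,3,14,26,74,18,14
Montreal,moderate,17,40,56,45,0,9,17,53,12
Montreal,low,1,20,15,12,58,39,9,28,61
Montreal,not_reported,32,39,25,41,28,25,0,1,14
New York City,high,28,1,13,3,3,14,61,16,17
New York City,moderate,22,46,19,58,0,14,37,39,21
New York City,low,11,30,9,14,58,14,2,36,42
New York City,not_reported,40,24,58,25,39,58,0,9,20
Paris,high,15,4,6,2,4,17,49,7,29
Paris,moderate,37,39,17,45,2,9,46,51,16
Paris,low,11,36,28,22,76,11,3,32,46
Paris,not_reported,37,21,49,31,17,62,1,9,10
Vancouver,high,33,5,5,2,6,13,33,10,11
Vancouver,moderate,19,28,35,39,0,17,56,40,15
Vancouver,low,25,22,12,13,68,25,11,45,47
Vancouver,not_reported,24,45,47,46,26,45,0,5,27
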