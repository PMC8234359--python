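compound,mw,rotor,hba,hbd,mr,tpsa,logd
S-CY3A,691.9,13,7,1,180.42,152.68,-1.96
S-CY5.5A,1054.36,18,13,1,241.21,256.18,-1.68
S-CY5A,547.79,11,1,0,185.18,23.32,-0.72
FAMA,413.38,3,6,3,109.52,105.09,-0.14
TAMRA,467.52,6,4,1,135.27,88.62,0.46
R6GA,462.6,7,2,1,144.59,38.33,1.07
CY3A,530.14,10,1,1,169.95,35.35,1.73
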