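compound,route,compartment,auc
S-CY3A,IMM,WB,4.56
S-CY3A,IY,WB,31.4
S-CY3A,IMM,Yolk,1.89
S-CY3A,IY,Yolk,23.8
S-CY3A,IMM,RoB,2.67
S-CY3A,IY,RoB,7.65
S-CY5.5A,IMM,WB,0
S-CY5.5A,IY,WB,5.45
S-CY5.5A,IMM,Yolk,0
S-CY5.5A,IY,Yolk,4.42
S-CY5.5A,IMM,RoB,0
S-CY5.5A,IY,RoB,1.02
S-CY5A,IMM,WB,0
S-CY5A,IY,WB,9.49
S-CY5A,IMM,Yolk,0
S-CY5A,IY,Yolk,7.82
S-CY5A,IMM,RoB,0
S-CY5A,IY,RoB,1.67
FAMA,IMM,WB,1.17
FAMA,IY,WB,27.8
FAMA,IMM,Yolk,0.36
FAMA,IY,Yolk,14.9
FAMA,IMM,RoB,0.84
FAMA,IY,RoB,6.93
TAMRA,IMM,WB,7.76
TAMRA,IY,WB,40.4
TAMRA,IMM,Yolk,4.98
TAMRA,IY,Yolk,29.1
TAMRA,IMM,RoB,2.78
TAMRA,IY,RoB,11.2
R6GA,IMM,WB,0.58
R6GA,IY,WB,5.76
R6GA,IMM,Yolk,0
R6GA,IY,Yolk,4.29
R6GA,IMM,RoB,0.58
R6GA,IY,RoB,1.48
CY3A,IMM,WB,20.9
CY3A,IY,WB,18.9
CY3A,IMM,Yolk,14.6
CY3A,IY,Yolk,15.7
CY3A,IMM,RoB,6.41
CY3A,IY,RoB,3.21
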