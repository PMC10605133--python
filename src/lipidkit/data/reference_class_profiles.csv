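class_code,tissue,wt_mean,hom_mean,stars
CE,B,0.087,0.115,
Cer,B,0.022,0.023,
CL,B,0.330,0.327,
DG,B,0.115,0.101,
PC-O,B,0.077,0.076,
PE-O,B,3.670,3.483,
HexCer,B,0.029,0.023,
LPC,B,0.231,0.239,
LPE,B,0.406,0.409,
LPI,B,0.029,0.024,
PA,B,0.052,0.046,
PC,B,8.254,7.902,
PE,B,2.612,2.590,
PG,B,0.082,0.089,
PI,B,0.438,0.364,
PS,B,3.071,3.009,
SHexCer,B,0.021,0.018,*
SM,B,0.614,0.617,
CE,C,0.131,0.182,
Cer,C,0.055,0.050,
CL,C,0.182,0.203,
DG,C,0.210,0.137,
PC-O,C,0.908,0.863,
PE-O,C,5.619,4.557,*
HexCer,C,0.040,0.028,*
LPC,C,0.251,0.262,
LPE,C,0.380,0.405,
LPI,C,0.042,0.033,
PA,C,0.158,0.092,
PC,C,8.312,7.994,
PE,C,3.254,2.822,
PG,C,0.096,0.097,
PI,C,0.925,0.817,
PS,C,4.182,3.832,
SHexCer,C,0.032,0.023,***
SM,C,0.186,0.194,
CE,SC,0.137,0.730,*
Cer,SC,0.063,0.054,
CL,SC,0.143,0.217,
DG,SC,0.445,0.251,*
PC-O,SC,0.245,0.218,
PE-O,SC,10.399,8.169,*
PI-O,SC,0.198,0.176,
HexCer,SC,0.151,0.128,
LPC,SC,0.598,0.505,
LPE,SC,1.065,0.853,
LPI,SC,0.054,0.040,*
PA,SC,2.891,1.065,*
PC,SC,9.829,8.323,*
PE,SC,4.621,3.724,
PG,SC,0.184,0.227,
PI,SC,1.421,1.194,
PS,SC,6.569,5.589,
SHexCer,SC,0.058,0.044,
SM,SC,0.893,1.056,
CE,SN,0.169,2.351,**
Cer,SN,0.011,0.012,
CL,SN,0.142,0.246,
DG,SN,0.466,0.174,***
PC-O,SN,0.613,0.287,**
PE-O,SN,12.154,4.209,***
HexCer,SN,0.193,0.102,***
LPC,SN,0.480,0.401,
LPE,SN,0.424,0.232,*
LPI,SN,0.035,0.023,*
PA,SN,4.295,0.342,*
PC,SN,14.912,6.426,***
PE,SN,3.277,1.245,**
PG,SN,0.059,0.164,**
PI,SN,1.146,0.684,*
PS,SN,2.740,2.980,
SHexCer,SN,0.070,0.037,**
SM,SN,2.468,1.771,
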