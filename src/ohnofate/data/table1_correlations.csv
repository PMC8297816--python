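family,r_ab,stars_ab,r_as,stars_as,r_bs,stars_bs,resp_a,resp_b,resp_s
myod,0.75,3,0.28,1,0.41,2,True,True,True
trim63,0.92,3,0.21,0,0.17,0,True,True,False
igfbp3,0.11,0,0.15,0,0.03,0,True,True,True
tgfb3,0.16,0,-0.25,0,-0.13,0,True,True,True
atf4,0.49,2,-0.24,0,-0.04,0,False,False,True
igf2bp2,0.97,3,0.34,2,0.28,1,True,True,True
igf2,0.53,2,-0.15,0,-0.11,0,True,True,False
mef2d,0.73,3,0.28,1,0.36,2,True,True,True
pik3ca,0.72,3,0.27,1,0.29,1,True,True,True
pip4k2a,0.71,3,0.27,1,0.28,1,True,True,True
raf1,0.42,2,-0.19,0,0.36,2,True,True,False
rictor,0.64,3,-0.08,0,0.05,0,True,True,False
rragc,0.48,2,0.00,0,-0.09,0,False,False,True
tgfb1,0.41,2,0.27,1,0.23,0,True,True,False
fst,0.38,2,-0.19,0,-0.23,0,True,True,False
grb2,0.91,3,-0.06,0,-0.05,0,True,True,False
eif3j,0.85,3,0.35,2,0.54,3,True,True,True
akt2,0.68,3,-0.28,1,-0.06,0,False,False,True
chuk,0.63,3,0.08,0,0.21,0,False,False,True
cdc42bpa,0.79,3,0.50,3,0.33,2,True,True,True
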