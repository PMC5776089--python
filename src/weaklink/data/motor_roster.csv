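name,x,y,z,radius
L_SMA,-6,-4,55,3
R_SMA,6,-4,61,3
L_M1,-3,-28,64,3
L_CMA,-12,-7,49,3
R_CMA,12,2,45,3
L_PMd,-39,-10,55,3
R_PMd,45,-1,52,3
L_PMv,-54,5,7,3
R_PMv,57,8,16,3
R_MFG,36,41,25,3
L_S1,-12,-43,67,3
L_SPL,-12,-43,64,3
L_IPC,-63,-28,31,3
R_IPC,57,-28,25,3
L_S2,-48,-28,22,3
R_S2,54,-28,25,3
L_Insula,-45,2,8,3
R_Insula,33,17,10,3
L_Putamen,-27,-1,13,3
R_Putamen,24,-1,13,3
L_Thalamus,-15,-13,4,3
L_Cerebellum,-33,-58,-26,3
R_Cerebellum,21,-34,-26,3
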