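analyte_id,model,a2,a1,a0,internal_standard_id,lod_ng_ml
PFBA,linear,0.0,0.8092,0.0579,MPFBA,0.6
PFPeA,linear,0.0,0.3435,0.0068,MPFBA,0.7
PFHxA,linear,0.0,1.103,0.122,MPFHxA,0.7
PFHpA,linear,0.0,0.7907,0.0382,MPFHxA,0.6
PFOA,linear,0.0,1.0968,0.1978,MPFOA,1.0
PFNA,quadratic,-0.0156,0.953,0.057,MPFNA,0.8
PFDA,linear,0.0,0.9312,0.0197,MPFDA,0.6
PFUdA,linear,0.0,0.9854,0.039,MPFUdA,0.6
PFDoA,linear,0.0,0.89,0.0311,MPFDoA,0.5
PFTrDA,linear,0.0,1.1157,0.008,MPFDoA,0.5
PFTeDA,linear,0.0,0.8752,0.013,MPFDoA,0.7
PFHxDA,linear,0.0,0.6599,-0.0098,MPFDoA,0.6
PFODA,linear,0.0,0.7385,-0.0222,MPFDoA,0.4
L-PFBS,linear,0.0,9.9377,0.0499,MPFHxS,0.5
L-PFHxS,quadratic,-0.0538,5.5136,0.0339,MPFHxS,0.4
L-PFOS,quadratic,-0.0165,1.0528,0.045,MPFOS,0.4
L-PFDS,quadratic,-0.018,1.0766,0.018,MPFOS,0.8
HFPO-DA,linear,0.0,0.1406,0.0051,MPFHxA,0.7
ADONA,linear,0.0,3.236,-0.1108,MPFOA,0.7
9Cl-PF3ONS,quadratic,0.0144,0.7061,0.0235,MPFOS,0.6
11Cl-PF3OUdS,linear,0.0,0.4769,0.0143,MPFOS,0.7
PF4OPeA,linear,0.0,0.4607,0.0111,MPFBA,0.5
PF5OHxA,linear,0.0,1.6888,0.0302,MPFHxA,0.7
PFEESA,linear,0.0,36.76,0.4631,MPFHxA,0.7
"3,6-OPFHpA",linear,0.0,0.0356,0.0001,MPFHxS,1.0
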