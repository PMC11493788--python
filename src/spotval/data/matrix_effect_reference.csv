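analyte_id,me_pct,me_rsd_pct,er_pct,er_rsd_pct
PFBA,131,13,98,18
PFPeA,180,19,91,18
PFHxA,128,12,93,22
PFHpA,169,22,109,20
PFOA,156,12,96,2
PFNA,152,18,82,21
PFDA,178,21,98,23
PFUdA,162,8,102,18
PFDoA,149,17,96,22
PFTrDA,130,12,83,5
PFTeDA,171,19,76,7
PFHxDA,145,19,77,23
PFODA,193,16,89,15
L-PFBS,178,18,84,8
L-PFHxS,131,23,90,7
L-PFOS,127,21,92,16
L-PFDS,148,13,84,2
HFPO-DA,84,10,103,16
ADONA,142,8,90,19
9Cl-PF3ONS,169,9,99,20
11Cl-PF3OUdS,186,18,101,8
PF4OPeA,166,10,96,13
PF5OHxA,167,5,94,18
PFEESA,138,19,98,11
"3,6-OPFHpA",143,22,92,17
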