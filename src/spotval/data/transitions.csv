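analyte_id,name,family,rt_min,precursor_mz,product_mz,ce_v,cxp_v,ordinal,internal_standard_id
PFBA,perfluoro-n-butanoic acid,perfluorocarboxylic acid,1.9,213.0,169.0,-15,-14,1,MPFBA
PFPeA,perfluoro-n-pentanoic acid,perfluorocarboxylic acid,3.5,263.0,219.0,-11,-14,1,MPFBA
PFHxA,perfluoro-n-hexanoic acid,perfluorocarboxylic acid,4.9,313.0,269.0,-12,-5,1,MPFHxA
PFHxA,perfluoro-n-hexanoic acid,perfluorocarboxylic acid,4.9,313.0,119.0,-26,-11,2,MPFHxA
PFHpA,perfluoro-n-heptanoic acid,perfluorocarboxylic acid,5.9,363.0,319.0,-12,-5,1,MPFHxA
PFHpA,perfluoro-n-heptanoic acid,perfluorocarboxylic acid,5.9,363.0,169.0,-16,-7,2,MPFHxA
PFOA,perfluoro-n-octanoic acid,perfluorocarboxylic acid,6.7,413.0,369.0,-14,-7,1,MPFOA
PFOA,perfluoro-n-octanoic acid,perfluorocarboxylic acid,6.7,413.0,169.0,-18,-7,2,MPFOA
PFNA,perfluoro-n-nonanoic acid,perfluorocarboxylic acid,7.3,463.0,419.0,-14,-7,1,MPFNA
PFNA,perfluoro-n-nonanoic acid,perfluorocarboxylic acid,7.3,463.0,219.0,-18,-7,2,MPFNA
PFDA,perfluoro-n-decanoic acid,perfluorocarboxylic acid,7.8,513.0,469.0,-14,-7,1,MPFDA
PFDA,perfluoro-n-decanoic acid,perfluorocarboxylic acid,7.8,513.0,219.0,-18,-7,2,MPFDA
PFUdA,perfluoro-n-undecanoic acid,perfluorocarboxylic acid,8.2,563.0,519.0,-18,-7,1,MPFUdA
PFUdA,perfluoro-n-undecanoic acid,perfluorocarboxylic acid,8.2,563.0,269.0,-18,-7,2,MPFUdA
PFDoA,perfluoro-n-dodecanoic acid,perfluorocarboxylic acid,8.7,613.0,569.0,-18,-7,1,MPFDoA
PFDoA,perfluoro-n-dodecanoic acid,perfluorocarboxylic acid,8.7,613.0,169.0,-26,-13,2,MPFDoA
PFTrDA,perfluoro-n-tridecanoic acid,perfluorocarboxylic acid,9.0,663.0,619.0,-20,-10,1,MPFDoA
PFTrDA,perfluoro-n-tridecanoic acid,perfluorocarboxylic acid,9.0,663.0,169.0,-35,-10,2,MPFDoA
PFTeDA,perfluoro-n-tetradecanoic acid,perfluorocarboxylic acid,9.3,713.0,669.0,-22,-10,1,MPFDoA
PFTeDA,perfluoro-n-tetradecanoic acid,perfluorocarboxylic acid,9.3,713.0,169.0,-35,-10,2,MPFDoA
PFHxDA,perfluoro-n-hexadecanoic acid,perfluorocarboxylic acid,9.8,813.0,769.0,-24,-10,1,MPFDoA
PFHxDA,perfluoro-n-hexadecanoic acid,perfluorocarboxylic acid,9.8,813.0,169.0,-32,-11,2,MPFDoA
PFODA,perfluoro-n-octadecanoic acid,perfluorocarboxylic acid,10.2,913.0,869.0,-26,-11,1,MPFDoA
PFODA,perfluoro-n-octadecanoic acid,perfluorocarboxylic acid,10.2,913.0,169.0,-36,-15,2,MPFDoA
L-PFBS,perfluoro-1-butanesulfonic acid,perfluorosulfonic acid,4.1,299.0,80.0,-55,-25,1,MPFHxS
L-PFBS,perfluoro-1-butanesulfonic acid,perfluorosulfonic acid,4.1,299.0,98.9,-55,-25,2,MPFHxS
L-PFHxS,perfluoro-1-hexanesulfonic acid,perfluorosulfonic acid,6.1,399.0,80.0,-74,-30,1,MPFHxS
L-PFHxS,perfluoro-1-hexanesulfonic acid,perfluorosulfonic acid,6.1,399.0,98.9,-74,-30,2,MPFHxS
L-PFOS,perfluoro-1-octanesulfonic acid,perfluorosulfonic acid,7.4,499.0,98.9,-108,-22,1,MPFOS
L-PFOS,perfluoro-1-octanesulfonic acid,perfluorosulfonic acid,7.4,499.0,80.0,-108,-22,2,MPFOS
L-PFDS,perfluoro-1-decanesulfonic acid,perfluorosulfonic acid,8.3,599.0,80.0,-118,-25,1,MPFOS
L-PFDS,perfluoro-1-decanesulfonic acid,perfluorosulfonic acid,8.3,599.0,98.9,-118,-25,2,MPFOS
HFPO-DA,"2,3,3,3-tetrafluoro-2-(1,1,2,2,3,3,3-heptafluoroproproxy) propanoic acid",replacement PFAS,5.3,329.0,169.0,-18,-11,1,MPFHxA
HFPO-DA,"2,3,3,3-tetrafluoro-2-(1,1,2,2,3,3,3-heptafluoroproproxy) propanoic acid",replacement PFAS,5.3,329.0,285.0,-8,-11,2,MPFHxA
ADONA,dodecafluoro-3H-4-8-dioxanonanoic acid,replacement PFAS,6.0,377.0,85.0,-37,-15,1,MPFOA
ADONA,dodecafluoro-3H-4-8-dioxanonanoic acid,replacement PFAS,6.0,377.0,251.0,-29,-15,2,MPFOA
9Cl-PF3ONS,9-chlorohexadecafluoro-3-oxanonane-1-sulfonic acid,replacement PFAS,7.7,531.0,351.0,-25,-15,1,MPFOS
9Cl-PF3ONS,9-chlorohexadecafluoro-3-oxanonane-1-sulfonic acid,replacement PFAS,7.7,531.0,83.0,-80,-20,2,MPFOS
11Cl-PF3OUdS,11-chloroeicosafluoro-3-oxaundecane-1-sulfonic acid,replacement PFAS,8.6,631.0,451.0,-25,-15,1,MPFOS
11Cl-PF3OUdS,11-chloroeicosafluoro-3-oxaundecane-1-sulfonic acid,replacement PFAS,8.6,631.0,83.0,-80,-20,2,MPFOS
PF4OPeA,perfluoro-4-oxapentanoic acid,perfluoroalkylether,2.5,229.0,85.0,-30,-15,1,MPFBA
PF4OPeA,perfluoro-4-oxapentanoic acid,perfluoroalkylether,2.5,229.0,197.0,-19,-13,2,MPFBA
PF5OHxA,perfluoro-5-oxahexanoic acid,perfluoroalkylether,4.0,279.0,85.0,-30,-15,1,MPFHxA
PF5OHxA,perfluoro-5-oxahexanoic acid,perfluoroalkylether,4.0,279.0,235.0,-11,-16,2,MPFHxA
PFEESA,perfluoro (2-ethoxyethane)sulfonic acid,perfluoroalkylether,4.7,315.0,135.0,-22,-11,1,MPFHxA
PFEESA,perfluoro (2-ethoxyethane)sulfonic acid,perfluoroalkylether,4.7,315.0,69.0,-60,-17,2,MPFHxA
"3,6-OPFHpA","perfluoro-3,6-dioxaheptanoic acid",perfluoroalkylether,4.8,295.0,201.0,-16,-7,1,MPFHxS
"3,6-OPFHpA","perfluoro-3,6-dioxaheptanoic acid",perfluoroalkylether,4.8,295.0,85.0,-29,-15,2,MPFHxS
MPFBA,perfluoro-n-(13C4) butanoic acid,internal standard,1.9,217.0,172.0,-15,-14,1,
MPFHxA,perfluoro-n-(1-2-13C2) hexanoic acid,internal standard,4.9,315.0,270.0,-12,-5,1,
MPFOA,perfluoro-n-(1-2-3-4-13C4) octanoic acid,internal standard,6.7,417.0,372.0,-14,-7,1,
MPFNA,perfluoro-n-(1-2-3-4-5-13C5) nonanoic acid,internal standard,7.3,468.0,423.0,-14,-7,1,
MPFDA,perfluoro-n-(1-2-13C2) decanoic acid,internal standard,7.8,515.0,470.0,-16,-5,1,
MPFUdA,perfluoro-n-(1-2-13C2) undecanoic acid,internal standard,8.2,565.0,520.0,-18,-7,1,
MPFDoA,perfluoro-n-(1-2-13C2) dodecanoic acid,internal standard,8.7,615.0,570.0,-18,-7,1,
MPFHxS,perfluoro-1-hexane (18O2) sulfonic acid,internal standard,6.1,403.0,103.0,-74,-30,1,
MPFOS,perfluoro-1-(1-2-3-4-13C4) octanesulfonic acid,internal standard,7.4,503.0,80.0,-108,-22,1,
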