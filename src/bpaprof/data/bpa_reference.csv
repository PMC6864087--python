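# Reference benzylphenoxyacetamide (BPA) series: structures transcribed from
# the IUPAC names given in the synthesis methods, plus analogs whose
# structures are unambiguously derivable from the running text (HR4 = PP1
# with the benzophenone carbonyl replaced by an ether oxygen; HR9 = PP1 with
# 4'-Cl replaced by 4'-F; HR34 = free base of HR35/HR36).  PP1 and HR40 name
# the same compound and are carried as two rows so both ids resolve.
# Compounds whose structures appear only in figure artwork and cannot be
# named from the text are excluded: HR3 (unassigned), HR6-HR8, HR10-HR31,
# HR33, HR37-HR39, HR41-HR47, HR57.
# Viability rows transcribe printed mean CV (% of vehicle control) and SD
# (percentage points) at the stated micromolar concentration; SD is blank
# where the text prints no SD.
id,name,smiles,region_a,region_b,region_c,region_d,salt,conc_um,mean_cv,sd_cv
FF,isopropyl 2-(4-(4-chlorobenzoyl)phenoxy)-2-methylpropanoate,CC(C)OC(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1,Cl,carbonyl,gem_dimethyl,isopropyl_ester,none,,,
FFA,2-(4-(4-chlorobenzoyl)phenoxy)-2-methylpropanoic acid,OC(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1,Cl,carbonyl,gem_dimethyl,carboxylic_acid,none,,,
AA,2-(4-(4-chlorobenzoyl)phenoxy)-2-methylpropanamide,NC(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1,Cl,carbonyl,gem_dimethyl,primary_amide,none,,,
MA,"2-(4-(4-chlorobenzoyl)phenoxy)-N,2-dimethylpropanamide",CNC(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1,Cl,carbonyl,gem_dimethyl,N_methyl,none,,,
DMA,"2-(4-(4-chlorobenzoyl)phenoxy)-N,N,2-trimethylpropanamide",CN(C)C(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1,Cl,carbonyl,gem_dimethyl,NN_dimethyl,none,,,
HR1,"2-(4-(cyclohexylmethyl)phenoxy)-N-(2-hydroxyethyl)-N,2-dimethylpropanamide",OCCN(C)C(=O)C(C)(C)Oc1ccc(CC2CCCCC2)cc1,H,reduced_ring,gem_dimethyl,N_methyl_N_hydroxyethyl,none,,,
HR2,"2-(4-(4-chlorobenzyl)phenoxy)-N-(2-hydroxyethyl)-N,2-dimethylpropanamide",OCCN(C)C(=O)C(C)(C)Oc1ccc(Cc2ccc(Cl)cc2)cc1,Cl,methylene,gem_dimethyl,N_methyl_N_hydroxyethyl,none,,,
HR4,"2-(4-(4-chlorophenoxy)phenoxy)-N-(2-hydroxyethyl)-N,2-dimethylpropanamide",OCCN(C)C(=O)C(C)(C)Oc1ccc(Oc2ccc(Cl)cc2)cc1,Cl,ether,gem_dimethyl,N_methyl_N_hydroxyethyl,none,25,58.5,
HR5,"2-(4-(4-chlorophenoxy)phenoxy)-N,N-bis(2-hydroxyethyl)-2-methylpropanamide",OCCN(CCO)C(=O)C(C)(C)Oc1ccc(Oc2ccc(Cl)cc2)cc1,Cl,ether,gem_dimethyl,NN_bis_hydroxyethyl,none,25,90.47,
HR9,"2-(4-(4-fluorobenzoyl)phenoxy)-N-(2-hydroxyethyl)-N,2-dimethylpropanamide",OCCN(C)C(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(F)cc2)cc1,F,carbonyl,gem_dimethyl,N_methyl_N_hydroxyethyl,none,25,35.55,
HR32,2-(4-(4-chlorobenzoyl)phenoxy)-N-(2-(diethylamino)ethyl)-2-methylpropanamide,CCN(CC)CCNC(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1,Cl,carbonyl,gem_dimethyl,N_diethylaminoethyl,none,25,0.17,
HR32,,,,,,,,10,41.49,7.94
HR32,,,,,,,,5,77.76,7.24
HR32,,,,,,,,1,96.80,6.51
HR34,2-(4-(4-chlorobenzoyl)phenoxy)-2-methyl-1-(4-methylpiperazin-1-yl)propan-1-one,CN1CCN(C(=O)C(C)(C)Oc2ccc(C(=O)c3ccc(Cl)cc3)cc2)CC1,Cl,carbonyl,gem_dimethyl,N_methylpiperazine,none,,,
HR35,4-(2-(4-(4-chlorobenzoyl)phenoxy)-2-methylpropanoyl)-1-methylpiperazin-1-ium chloride,C[NH+]1CCN(C(=O)C(C)(C)Oc2ccc(C(=O)c3ccc(Cl)cc3)cc2)CC1.[Cl-],Cl,carbonyl,gem_dimethyl,N_methylpiperazinium,chloride,10,56.26,0.59
HR35,,,,,,,,5,79.34,1.70
HR35,,,,,,,,1,93.64,2.08
HR36,"4-(2-(4-(4-chlorobenzoyl)phenoxy)-2-methylpropanoyl)-1,1-dimethylpiperazin-1-ium iodide",C[N+]1(C)CCN(C(=O)C(C)(C)Oc2ccc(C(=O)c3ccc(Cl)cc3)cc2)CC1.[I-],Cl,carbonyl,gem_dimethyl,NN_dimethylpiperazinium,iodide,25,98,
PP1,"2-(4-(4-chlorobenzoyl)phenoxy)-N-(2-hydroxyethyl)-N,2-dimethylpropanamide",OCCN(C)C(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1,Cl,carbonyl,gem_dimethyl,N_methyl_N_hydroxyethyl,none,25,1.04,
PP1,,,,,,,,10,43.67,1.88
PP1,,,,,,,,5,70.03,2.04
PP1,,,,,,,,1,98.36,1.61
HR40,"2-(4-(4-chlorobenzoyl)phenoxy)-N-(2-hydroxyethyl)-N,2-dimethylpropanamide (PP1)",OCCN(C)C(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1,Cl,carbonyl,gem_dimethyl,N_methyl_N_hydroxyethyl,none,25,1.04,
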