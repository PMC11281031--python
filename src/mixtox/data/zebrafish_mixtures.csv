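chemical_1,conc_1_uM,chemical_2,conc_2_uM,ai_cptm,ai_hnn,rf,bagging,adaboost,experiment,interaction
Pyraclostrobin,0.01,Fenpropathrin,5,0,0,1,1,1,0,no interaction
Pyraclostrobin,0.01,"Alpha, alpha'-(1-methylethylenediimino)di-ortho-cresol",2.5,0,0,1,1,1,0,no interaction
Pyraclostrobin,0.01,Paclobutrazol,50,1,1,1,1,1,0,inconclusive
Pyraclostrobin,0.01,"2,4,6-Tribromophenol",2,1,1,1,1,1,1,inconclusive
Pyraclostrobin,0.01,Pyridaben,0.05,0,1,1,1,1,0,inconclusive
Pyraclostrobin,0.01,Butachlor,100,1,1,0,0,0,1,no interaction
Pyraclostrobin,0.01,Tetramethrin,5,1,0,0,1,1,1,inconclusive
Pyraclostrobin,0.01,Dicyclohexyl Phthalate (DCHP),100,1,0,1,1,0,1,inconclusive
Fenpropathrin,5,"Alpha, alpha'-(1-methylethylenediimino)di-ortho-cresol",2.5,1,1,1,0,1,1,additive
Fenpropathrin,5,Paclobutrazol,50,1,1,1,1,1,1,additive
Fenpropathrin,5,"2,4,6-Tribromophenol",2,1,1,1,1,1,1,additive
Fenpropathrin,5,Pyridaben,0.05,1,1,1,1,1,0,no interaction
Fenpropathrin,5,Butachlor,100,1,1,0,0,0,1,additive
Fenpropathrin,5,Tetramethrin,5,1,1,1,1,1,1,synergistic
Fenpropathrin,5,Dicyclohexyl Phthalate (DCHP),100,1,1,1,1,0,1,synergistic
"Alpha, alpha'-(1-methylethylenediimino)di-ortho-cresol",2.5,Paclobutrazol,50,1,1,1,1,1,1,additive
"Alpha, alpha'-(1-methylethylenediimino)di-ortho-cresol",2.5,"2,4,6-Tribromophenol",2,1,1,1,1,1,1,additive
"Alpha, alpha'-(1-methylethylenediimino)di-ortho-cresol",2.5,Pyridaben,0.05,0,0,0,1,1,0,inconclusive
"Alpha, alpha'-(1-methylethylenediimino)di-ortho-cresol",2.5,Butachlor,100,0,0,1,0,0,1,additive
"Alpha, alpha'-(1-methylethylenediimino)di-ortho-cresol",2.5,Tetramethrin,5,0,0,0,0,1,0,no interaction
"Alpha, alpha'-(1-methylethylenediimino)di-ortho-cresol",2.5,Dicyclohexyl Phthalate (DCHP),100,0,0,0,0,0,0,no interaction
Paclobutrazol,50,"2,4,6-Tribromophenol",2,0,0,1,1,1,0,no interaction
Paclobutrazol,50,Pyridaben,0.05,1,1,1,1,1,1,additive
Paclobutrazol,50,Butachlor,100,1,1,1,1,1,1,synergistic
Paclobutrazol,50,Tetramethrin,5,0,0,1,0,1,0,additive
Paclobutrazol,50,Dicyclohexyl Phthalate (DCHP),100,1,1,1,0,1,0,additive
"2,4,6-Tribromophenol",2,Pyridaben,0.05,1,1,1,1,1,0,no interaction
"2,4,6-Tribromophenol",2,Butachlor,100,1,1,0,0,0,1,synergistic
"2,4,6-Tribromophenol",2,Tetramethrin,5,1,1,1,1,1,1,additive
"2,4,6-Tribromophenol",2,Dicyclohexyl Phthalate (DCHP),100,1,1,1,0,0,1,no interaction
Pyridaben,0.05,Butachlor,100,1,1,1,1,1,1,synergistic
Pyridaben,0.05,Tetramethrin,5,1,1,1,1,0,0,inconclusive
Pyridaben,0.05,Dicyclohexyl Phthalate (DCHP),100,1,1,1,1,0,0,inconclusive
Butachlor,100,Tetramethrin,5,1,1,1,0,1,1,synergistic
Butachlor,100,Dicyclohexyl Phthalate (DCHP),100,1,1,1,1,1,1,synergistic
Tetramethrin,5,Dicyclohexyl Phthalate (DCHP),100,1,1,1,1,1,1,inconclusive
Perfluorooctane sulfonic acid (PFOS),53,Perfluorooctanoic acid (PFOA),187.5,1,1,1,1,1,1,synergistic
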