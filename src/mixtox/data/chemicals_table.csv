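name,casrn
Pyraclostrobin,175013-18-0
Fenpropathrin,39515-41-8
"Alpha, alpha'-(1-methylethylenediimino)di-ortho-cresol",94-91-7
Paclobutrazol,76738-62-0
"2,4,6-Tribromophenol",118-79-6
Pyridaben,96489-71-3
Butachlor,23184-66-9
Tetramethrin,7696-12-0
Dicyclohexyl Phthalate (DCHP),84-61-7
Perfluorooctanoic acid (PFOA),335-67-1
Perfluorooctane sulfonic acid (PFOS),1763-23-1
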