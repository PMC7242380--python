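organism_id	classification	role	lipid
Huberarchaeum_crystalense	Ca. Huberarchaeum crystalense	primary	2G-1uns-ext-AR
Huberarchaeum_crystalense	Ca. Huberarchaeum crystalense	secondary	1G-1pentose-AR
Huberarchaeum_crystalense	Ca. Huberarchaeum crystalense	secondary	2G-ext-AR
Huberarchaeum_crystalense	Ca. Huberarchaeum crystalense	secondary	C30:0-PG
Forterrea_multitransposorum	Ca. Forterrea multitransposorum	primary	C36:4-PC
Forterrea_multitransposorum	Ca. Forterrea multitransposorum	primary	C44:12-DGCC
Bacteria_1	Bacteria	primary	C44:12-DGTA
Bacteria_1	Bacteria	secondary	C32:2-DGTA
Bacteria_1	Bacteria	secondary	C30:1-DGTA
Bacteria_1	Bacteria	secondary	C32:3-DGCC
Bacteria_1	Bacteria	secondary	C32:3-DGTA
Bacteria_1	Bacteria	secondary	C32:4-DGTA
Bacteria_1	Bacteria	secondary	C34:4-DGCC
Bacteria_1	Bacteria	secondary	C34:5-DGTA
Bacteria_1	Bacteria	secondary	C34:6-DGTA
Bacteria_1	Bacteria	secondary	C36:5-DGCC
Bacteria_1	Bacteria	secondary	C36:6-DGCC
Bacteria_1	Bacteria	secondary	C36:6-DGTA
Bacteria_1	Bacteria	secondary	C36:7-DGTA
Bacteria_1	Bacteria	secondary	C36:8-DGTA
Bacteria_1	Bacteria	secondary	C37:2-DGTA
Bacteria_1	Bacteria	secondary	C38:7-DGCC
Bacteria_1	Bacteria	secondary	C40:10-DGTA
Bacteria_1	Bacteria	secondary	C42:11-DGTA
Bacteria_1	Bacteria	secondary	C42:11-PC
Bacteria_1	Bacteria	secondary	C36:7-DGCC
Bacteria_2	Bacteria	primary	C63:3-DPG
Bacteria_3	Bacteria	primary	lyso_C18:2-DGTA
Bacteroidetes_1	Bacteroidetes	primary	C36:3-PE
Bacteroidetes_1	Bacteroidetes	primary	C36:4-PE
Bacteroidetes_1	Bacteroidetes	secondary	C30:1-PE
Bacteroidetes_1	Bacteroidetes	secondary	C34:3-PE
Bacteroidetes_1	Bacteroidetes	secondary	C34:4-PE
Bacteroidetes_1	Bacteroidetes	secondary	C30:2-PE
Bacteroidetes_1	Bacteroidetes	secondary	C32:4-PE
Bacteroidetes_1	Bacteroidetes	secondary	C32:5-PE
Citromicrobium_1	Citromicrobium	primary	C32:1-2Gly-DAG
Citromicrobium_1	Citromicrobium	primary	C32:2-2Gly-DAG
Citromicrobium_1	Citromicrobium	primary	C34:4-2Gly-DAG
Citromicrobium_1	Citromicrobium	primary	C34:5-2Gly-DAG
Citromicrobium_1	Citromicrobium	primary	C34:6-2Gly-DAG
Citromicrobium_1	Citromicrobium	primary	C36:6-2Gly-DAG
Citromicrobium_1	Citromicrobium	primary	C36:7-2Gly-DAG
Citromicrobium_1	Citromicrobium	primary	lyso_C20:4-DGCC
Citromicrobium_1	Citromicrobium	secondary	C38:7-2Gly-DAG
Citromicrobium_1	Citromicrobium	secondary	C42:11-DGCC
Citromicrobium_1	Citromicrobium	secondary	C30:1-2Gly-DAG
Citromicrobium_1	Citromicrobium	secondary	C30:2-2Gly-DAG
Citromicrobium_1	Citromicrobium	secondary	C32:3-2Gly-DAG
Citromicrobium_1	Citromicrobium	secondary	C38:9-DGCC
Citromicrobium_1	Citromicrobium	secondary	C61:0-DPG
Citromicrobium_1	Citromicrobium	secondary	C38:8-2Gly-DAG
Flavobacteriaceae_1	Flavobacteriaceae	primary	C63:4-DPG
Flavobacteriaceae_1	Flavobacteriaceae	secondary	C29:0-PE
Flavobacteriaceae_2	Flavobacteriaceae	primary	C65:4-DPG
Gallionellaceae_1	Gallionellaceae	primary	C25:0-OL
Gallionellaceae_1	Gallionellaceae	primary	C26:0-OL
Gallionellaceae_1	Gallionellaceae	primary	C26:1-OL
Gallionellaceae_1	Gallionellaceae	primary	C27:0-OL
Gallionellaceae_1	Gallionellaceae	primary	C27:1-OL
Gallionellaceae_1	Gallionellaceae	primary	C29:1-OL
Gallionellaceae_1	Gallionellaceae	primary	C30:0-OL
Gallionellaceae_1	Gallionellaceae	secondary	C30:1-OL
Gallionellaceae_1	Gallionellaceae	secondary	C32:2-OL
Gallionellaceae_1	Gallionellaceae	secondary	C28:1-OL
Gallionellaceae_1	Gallionellaceae	secondary	C28:0-OL
Gallionellaceae_1	Gallionellaceae	secondary	C34:2-OL
Gallionellaceae_1	Gallionellaceae	secondary	C29:0-OL
Gallionellaceae_1	Gallionellaceae	secondary	C28:1-PE
Gallionellaceae_1	Gallionellaceae	secondary	C30:2-OL
Gallionellaceae_1	Gallionellaceae	secondary	C33:2-PE
Gallionellaceae_2	Gallionellaceae	primary	C38:6-PC
Gallionellaceae_2	Gallionellaceae	secondary	C34:1-DGCC
Gallionellaceae_2	Gallionellaceae	secondary	C34:2-PC
Gallionellaceae_2	Gallionellaceae	secondary	AEG_C36:2-2G
Gallionellaceae_3	Gallionellaceae	primary	C62:3-DPG
Gallionellaceae_3	Gallionellaceae	primary	C64:3-DPG
Gallionellaceae_3	Gallionellaceae	primary	C66:4-DPG
Gallionellaceae_3	Gallionellaceae	secondary	C33:3-DGTS
Gallionellaceae_3	Gallionellaceae	secondary	C68:4-DPG
Hydrogenophilceae_1	Hydrogenophilceae	primary	C60:3-DPG
Hydrogenophilceae_1	Hydrogenophilceae	primary	C64:4-DPG
Proteobacteria_1	Proteobacteria	primary	C58:1-DPG
Proteobacteria_1	Proteobacteria	primary	C62:4-DPG
Proteobacteria_2	Proteobacteria	primary	lyso_C21:4-DGTS
Proteobacteria_2	Proteobacteria	secondary	C30:2-DGTS
Proteobacteria_3	Proteobacteria	primary	lyso_C22:6-DGTS
Proteobacteria_3	Proteobacteria	secondary	lyso_C21:5-DGTS
Proteobacteria_3	Proteobacteria	secondary	lyso_C16:2-DGTS
Falkowbacteria_OD1_1	Falkowbacteria (OD1)	primary	lyso_C16:0-DGTS
Kaiserbacteria_OD1_1	Kaiserbacteria (OD1)	primary	lyso_C16:0-DGTA
Kaiserbacteria_OD1_1	Kaiserbacteria (OD1)	secondary	lyso_C16:0-DGCC
Kaiserbacteria_OD1_2	Kaiserbacteria (OD1)	primary	lyso_C20:4-DGTS
Kaiserbacteria_OD1_2	Kaiserbacteria (OD1)	secondary	lyso_C16:1-DGTS
Kaiserbacteria_OD1_2	Kaiserbacteria (OD1)	secondary	lyso_C18:3-DGTS
Parcubacteria_1	Parcubacteria	primary	C30:0-DGCC
Parcubacteria_1	Parcubacteria	secondary	lyso_C16:3-DGTS
Parcubacteria_2	Parcubacteria	primary	C47:15-DGTA
Parcubacteria_2	Parcubacteria	secondary	C36:5-PG
Parcubacteria_2	Parcubacteria	secondary	C36:4-PG
Parcubacteria_3	Parcubacteria	primary	lyso_C16:2-DGCC
Parcubacteria_3	Parcubacteria	primary	lyso_C18:3-DGCC
Parcubacteria_3	Parcubacteria	primary	lyso_C18:4-DGCC
Parcubacteria_3	Parcubacteria	primary	lyso_C20:5-DGCC
Parcubacteria_3	Parcubacteria	secondary	lyso_C20:5-DGTA
Parcubacteria_3	Parcubacteria	secondary	lyso_C16:1-DGTA
Parcubacteria_3	Parcubacteria	secondary	lyso_C16:1-DGCC
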