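drugbank_id,name,smiles,adverse_event_flag,p_published,prediction_published,smiles_note
DB00279,Liothyronine,N[C@@H](Cc1cc(I)c(Oc2ccc(O)c(I)c2)c(I)c1)C(=O)O,reported,-0.001,non-sensitizer,curated from name/DrugBank ID
DB01407,Clenbuterol,CC(C)(C)NCC(O)c1cc(Cl)c(N)c(Cl)c1,reported,0.589,sensitizer,curated from name/DrugBank ID
DB00250,Dapsone,Nc1ccc(S(=O)(=O)c2ccc(N)cc2)cc1,reported,0.700,sensitizer,curated from name/DrugBank ID
DB00295,Morphine,CN1CC[C@]23c4c5ccc(O)c4O[C@H]2[C@@H](O)C=C[C@H]3[C@H]1C5,reported,0.580,sensitizer,curated from name/DrugBank ID
DB00327,Hydromorphone,CN1CC[C@]23c4c5ccc(O)c4O[C@H]2C(=O)CC[C@H]3[C@H]1C5,reported,0.595,sensitizer,curated from name/DrugBank ID
DB00481,Raloxifene,Oc1ccc2c(c1)sc(-c1ccc(O)cc1)c2C(=O)c1ccc(OCCN2CCCCC2)cc1,reported,0.977,sensitizer,curated from name/DrugBank ID
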