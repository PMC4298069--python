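id,cas,name,smiles,label,ec3,split,epsilon_homo,p_published,smiles_note
1,101-80-4,"4,4'-Diaminodiphenyl ether",Nc1ccc(Oc2ccc(N)cc2)cc1,sensitizer,,train,-0.262,1.0694,curated from name/CAS
2,106-47-8,4-Chloroaniline,Nc1ccc(Cl)cc1,sensitizer,6.5,train,-0.289,0.6563,curated from name/CAS
3,150-13-0,4-Aminobenzoic acid,Nc1ccc(C(=O)O)cc1,non-sensitizer,,train,-0.306,0.3962,curated from name/CAS
4,369-36-8,2-Fluoro-5-nitroaniline,Nc1cc([N+](=O)[O-])ccc1F,non-sensitizer,,train,-0.325,0.1055,curated from name/CAS
5,538-41-0,"4,4'-Diaminoazobenzene",Nc1ccc(/N=N/c2ccc(N)cc2)cc1,sensitizer,,train,-0.258,1.1306,curated from name/CAS
6,62-53-3,Aniline,Nc1ccccc1,sensitizer,89,train,-0.286,0.7022,curated from name/CAS
7,79456-26-1,3-Chloro-5-(trifluoromethyl)-2-pyridinamine,Nc1ncc(C(F)(F)F)cc1Cl,non-sensitizer,,train,-0.326,0.0902,curated from name/CAS
8,2050-14-8,"2,2'-Azodiphenol",Oc1ccccc1/N=N/c1ccccc1O,sensitizer,27.9,train,-0.294,0.5798,curated from name/CAS
9,55845-90-4,2-(N-Benzyl-N-ethylamino)-3'-hydroxyacetophenone hydrochloride,CCN(Cc1ccccc1)CC(=O)c1cccc(O)c1.Cl,non-sensitizer,,train,-0.316,0.2432,curated from name/CAS
10,69-72-7,Salicylic acid,OC(=O)c1ccccc1O,non-sensitizer,,train,-0.343,-0.1699,curated from name/CAS
11,90-15-3,1-Naphthol,Oc1cccc2ccccc12,sensitizer,1.3,train,-0.274,0.8858,curated from name/CAS
12,94-13-3,Propylparaben,CCCOC(=O)c1ccc(O)cc1,non-sensitizer,,train,-0.329,0.0443,curated from name/CAS
13,97-54-1,Isoeugenol,C/C=C/c1ccc(O)c(OC)c1,sensitizer,3.5,train,-0.277,0.8399,curated from name/CAS
14,99-96-7,4-Hydroxybenzoic acid,OC(=O)c1ccc(O)cc1,non-sensitizer,,train,-0.341,-0.1393,curated from name/CAS
15,186743-26-0,3-Methyleugenol,C=CCc1cc(OC)c(O)c(C)c1,sensitizer,32,train,-0.294,0.5798,curated from name/CAS
16,101-77-9,"4,4'-Diaminodiphenylmethane",Nc1ccc(Cc2ccc(N)cc2)cc1,sensitizer,,test,-0.266,1.0082,curated from name/CAS
17,121-57-3,Sulphanilic acid,Nc1ccc(S(=O)(=O)O)cc1,non-sensitizer,,test,-0.322,0.1514,curated from name/CAS
18,537-65-5,"4,4'-Diaminodiphenylamine",Nc1ccc(Nc2ccc(N)cc2)cc1,sensitizer,,test,-0.243,1.3601,curated from name/CAS
19,60-09-3,4-Aminoazobenzene,Nc1ccc(/N=N/c2ccccc2)cc1,sensitizer,,test,-0.276,0.8552,curated from name/CAS
20,63-74-1,Sulfanilamide,Nc1ccc(S(N)(=O)=O)cc1,non-sensitizer,,test,-0.307,0.3809,curated from name/CAS
21,94-09-7,Benzocaine,CCOC(=O)c1ccc(N)cc1,non-sensitizer,,test,-0.303,0.4421,curated from name/CAS
22,15128-82-2,3-Hydroxy-2-nitropyridine,Oc1cccnc1[N+](=O)[O-],non-sensitizer,,test,-0.362,-0.4606,curated from name/CAS
23,2785-87-7,Dihydroeugenol,CCCc1ccc(O)c(OC)c1,sensitizer,12.45,test,-0.288,0.6716,curated from name/CAS
24,619-14-7,3-Hydroxy-4-nitrobenzoic acid,OC(=O)c1ccc([N+](=O)[O-])c(O)c1,non-sensitizer,,test,-0.371,-0.5983,curated from name/CAS
25,80-05-7,Bisphenol A,CC(C)(c1ccc(O)cc1)c1ccc(O)cc1,sensitizer,,test,-0.287,0.6869,curated from name/CAS
26,93-51-6,2-Methoxy-4-methylphenol,COc1cc(C)ccc1O,sensitizer,5.8,test,-0.288,0.6716,curated from name/CAS
27,97-53-0,Eugenol,C=CCc1ccc(O)c(OC)c1,sensitizer,13.95,test,-0.296,0.5492,curated from name/CAS
28,99-76-3,Methyl 4-hydroxybenzoate,COC(=O)c1ccc(O)cc1,non-sensitizer,,test,-0.329,0.0443,curated from name/CAS
29,119-36-8,Methyl salicylate,COC(=O)c1ccccc1O,non-sensitizer,,test,-0.326,0.0902,curated from name/CAS
30,831-82-3,4-Phenoxyphenol,Oc1ccc(Oc2ccccc2)cc1,sensitizer,,test,-0.293,0.5951,curated from name/CAS
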