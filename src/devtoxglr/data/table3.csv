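casrn,chemical,dt_class,hpst_tc50_uM,hpst_ic50_uM,hpst_call,devtox_cc50_uM,devtox_ac50_uM,devtox_call
50-76-0,Actinomycin D,Pos,<0.01,<0.01,TP,4.8e-4,3.7e-5,TP
25316-40-9,Doxorubicin,Pos,<0.3,0.3,TP,3.3e-3,1.9e-3,TP
302-79-4,All-Trans-Retinoic Acid,Pos,33,0.07,TP,5.53,0.10,TP
4759-48-2,13-cis Retinoic Acid,Pos,140,0.2,TP,10.24,0.16,TP
59-14-3,5-Bromo-2'-deoxyuridine,Pos,3.4,0.2,TP,9.37,0.55,TP
284461-73-0,Sorafenib,Pos,<2,<2,TP,0.61,0.62,TP
341031-54-7,Sunitinib,Pos,3.6,2.8,TP,1.26,0.63,TP
56-53-1,Diethylstilbestrol,Pos,4.4,4.4,TP,0.71,0.64,TP
302962-49-8,Dasatinib,Pos,<1,<1,TP,0.05,0.72,TP
50-35-1,Thalidomide,Pos,>200,0.5,TP,>200,1.64,TP
146939-27-7,Ziprasidone,Pos,5.1,2.8,TP,2.42,3.57,TP
443913-73-3,Vandetanib,Pos,4.4,3.5,TP,4.32,4.90,TP
184475-35-2,Gefitinib,Pos,10,10,TP,6.60,5.75,TP
51-21-8,5-Fluorouracil,Pos,0.7,0.6,TP,5.72,8.48,TP
87051-43-2,Ritanserin,Pos,27,7.3,TP,9.47,9.98,TP
220127-57-1,Imatinib,Pos,22,11,TP,13.41,13.45,TP
329-89-5,6-Aminonicotinamide,Pos,8,7,TP,23.85,16.61,TP
866405-64-3,Dorsomorphin,Pos,2.4,0.3,TP,16.7,17.1,TP
21535-47-7,Mianserin,Pos,60,3.4,TP,33.56,34.85,TP
298-46-4,Carbamazepine,Pos,0.19,0.08,TP,136.8,102.7,TP
99-66-1,Valproic Acid,Pos,3.3,2.6,TP,>200,123.9,TP
59277-89-3,Acyclovir,Neg,>200,>200,TN,>200,>200,TN
50-78-2,Aspirin,Neg,>200,>200,TN,>200,>200,TN
58-08-2,Caffeine,Neg,>400,>400,TN,>200,>200,TN
59-30-3,Folic Acid,Neg,84,39,TN,>200,>200,TN
59-67-6,Niacin,Neg,>200,>200,TN,>200,>200,TN
113-98-4,Penicillin G,Neg,>400,>400,TN,>200,>200,TN
81-07-2,Saccharin,Neg,>400,>400,TN,>200,>200,TN
189188-57-6,Tegaserod Maleate,Neg,4.5,4.6,FP,5.06,5.32,FP
668985-31-7,Esomeprazole,Neg,101,32,TN,38.5,33.8,FP
74050-98-9,Ketanserin,Neg,>200,>200,TN,57.5,36.6,FP
154-23-4,Cianidanol,Neg,200,97,TN,193.6,92.9,FP
41372-08-1,Methyldopa,Neg,462,272,TN,>200,113.1,FP
15687-27-1,Ibuprofen,Neg,>200,>200,TN,79.4,161.8,FP
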