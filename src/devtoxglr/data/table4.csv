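casrn,chemical,dt_class,qp_cv_uM,qp_ti_uM,qp_call,devtox_cc_uM,devtox_acc_uM,devtox_call
302-79-4,All-Trans-Retinoic Acid,Pos,NA,0.003,TP,3.84,0.04,TP
50-35-1,Thalidomide,Pos,NA,1.27,TP,NA,0.25,TP
69-74-9,Cytarabine,Pos,0.083,0.054,TP,0.05,0.46,TP
56-53-1,Diethylstilbestrol,Pos,NA,NA,FN,0.60,0.54,TP
75330-75-5,Lovastatin,Pos,NA,5.1,TP,0.71,0.93,TP
51-21-8,5-Fluorouracil,Pos,1.45,2.02,TP,20.34,7.07,TP
53-86-1,Indomethacin,Pos,44.1,72.7,TP,8.70,9.38,TP
19774-82-4,Amiodarone,Pos,NA,5.1,TP,11.14,14.22,TP
147-24-0,Diphenhydramine,Pos,3.76,0.588,TP,14.34,16.78,TP
55-98-1,Busulfan,Pos,4.91,2.31,TP,5.79,25.26,TP
80-05-7,Bisphenol A,Pos,39.4,NA,FN,21.12,31.75,TP
13292-46-1,Rifampicin,Pos,NA,2.46,TP,18.11,37.85,TP
298-46-4,Carbamazepine,Pos,NA,2.29,TP,57.78,64.02,TP
4376-20-9,MEHP,Pos,NA,167,TP,61.55,76.33,TP
81-81-2,Warfarin,Pos,NA,NA,FN,197.75,93.33,TP
99-66-1,Valproic Acid,Pos,271,155,TP,NA,177.33,TP
57-41-0,"5,5-Diphenylhydantoin",Pos,NA,NA,FN,191.82,201.56,TP
57-55-6,"1,2-Propylene glycol",Neg,246664,327552,TN,NA,NA,TN
103-90-2,Acetaminophen,Neg,NA*,NA,TN,NA,NA,TN
79-06-1,Acrylamide,Neg,NA,NA,TN,NA,NA,TN
50-78-2,Aspirin,Neg,NA*,NA,TN,NA,NA,TN
58-08-2,Caffeine,Neg,NA,NA,TN,NA,NA,TN
464-49-3,D-Camphor,Neg,NA,NA,TN,NA,NA,TN
131-11-3,Dimethyl Phthalate,Neg,NA,NA,TN,NA,NA,TN
59-30-3,Folic Acid,Neg,NA,NA,TN,NA,NA,TN
54-85-3,Isoniazid,Neg,NA*,NA,TN,NA,NA,TN
81-07-2,Saccharin,Neg,NA,NA,TN,NA,NA,TN
69-72-7,Salicylic Acid,Neg,1795,513,TN,NA,NA,TN
599-79-1,Sulfasalazine,Neg,NA*,NA,TN,NA,NA,TN
68-26-8,Retinol,Neg,NA,NA,TN,12.63,13.05,FP
94-26-8,Butylparaben,Neg,NA,NA,TN,NA,34.47,FP
51-52-5,6-Propyl-2-thiouracil,Pos,NA,NA,FN,NA,NA,FN
10043-35-3,Boric acid,Pos,NA,NA,FN,NA,NA,FN
4449-51-8,Cyclopamine,Pos,NA,NA,FN,NA,NA,FN
6055-19-2,Cyclophosphamide,Pos,NA*,NA,FN,100.19,NA,FN
2392-39-4,Dexamethasone,Pos,21.8,37.7,TP,13.83,NA,FN
107-21-1,Ethylene Glycol,Pos,NA,NA,FN,NA,NA,FN
127-07-1,Hydroxyurea,Pos,237,74.9,TP,64.54,NA,FN
133073-73-1,Methotrexate,Pos,0.062,0.059,TP,0.35,NA,FN
3056-17-5,Stavudine,Pos,NA,32.5,TP,90.28,NA,FN
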