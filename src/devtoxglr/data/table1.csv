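chemical,casrn,dtxsid,dt_class,fda_category,ic50_uM,pct_max_inhibition,call
All-Trans Retinoic Acid,302-79-4,DTXSID7021239,Pos,X,0.16,93,TP
Lenalidomide,191732-72-6,DTXSID8046664,Pos,X,0.13,44,TP
Pomalidomide,19171-19-8,DTXSID40893458,Pos,X,0.05,81,TP
Thalidomide,50-35-1,DTXSID9022524,Pos,X,1.71,58,TP
Aspirin,50-78-2,DTXSID5020108,Neg,C,NA,NA,TN
Caffeine,58-08-2,DTXSID0020232,Neg,B,NA,NA,TN
Folic Acid,59-30-3,DTXSID0022519,Neg,A,NA,NA,TN
Saccharin,81-07-2,DTXSID5021251,Neg,A,NA,NA,TN
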