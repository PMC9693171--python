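category,category_name,UR,n_taxa,median,mean,sd,cv_pct
FO,Food and drinks,524,57,12,13.1,4.8,37
MD,Medicine,285,48,6,7.1,4.1,58
AL,Alcoholic drinks,90,16,2,2.2,1.1,51
AF,Animal feed,201,33,4,5.0,2.9,57
CT,Construction or hand craft,31,10,0,0.8,1.4,176
CE,Ceremonies,85,11,2,2.1,1.5,69
OT,Other not specified,43,18,1,1.1,1.4,130
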