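analyte,is_variation_pct,intraday_precision_pct,intraday_accuracy_pct,interday_precision_pct,interday_accuracy_pct,lod_ng_ml,loq_ng_ml,linearity_lo_ng_ml,linearity_hi_ng_ml
11-deoxycortisol,4,5,7,7,8,0.01,0.05,0.05,1000
17-OH-progesterone,3,5,6,6,8,0.01,0.05,0.05,1000
aldosterone,3,3,6,7,8,0.02,0.05,0.05,1000
androstenedione,4,4,7,7,8,0.05,0.1,0.1,2000
corticosterone,4,4,5,6,7,0.05,0.1,0.1,2000
cortisol,3,3,4,6,7,1,5,5,7000
DHEA,3,5,6,7,8,0.1,1,1,5000
DHEAS,4,5,7,7,7,1,10,10,7000
progesterone,3,4,7,6,7,0.01,0.05,0.05,1000
testosterone,3,5,6,7,8,0.01,0.05,0.05,1000
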