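model,label,accuracy,f2_score,auc_roc,topsis_score,rank
Model10,PCA,0.9790,0.9832,0.9885,0.9679,1
Model16,SVD,0.9720,0.9720,0.9910,0.9465,3
Model17,FAST ICA,0.9825,0.9930,0.9815,0.9270,4
Model18,ISOMAP,0.9825,0.9930,0.9841,0.9466,2
Model19,LLE,0.9335,0.9292,0.9656,0.7418,5
Model20,UMAP,0.8147,0.7015,0.9075,0.0000,6
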