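model,label,accuracy,f2_score,auc_roc,topsis_score,rank
Model10,PCA,0.8835,0.8461,0.9463,0.8871,1
Model16,SVD,0.8771,0.8279,0.9443,0.7124,3
Model17,FAST ICA,0.8412,0.7871,0.9030,0.3368,6
Model18,ISOMAP,0.8188,0.8283,0.8971,0.5819,4
Model19,LLE,0.8600,0.8460,0.9245,0.8291,2
Model20,UMAP,0.7988,0.8568,0.8320,0.5377,5
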