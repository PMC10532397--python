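model,label,accuracy,f2_score,auc_roc,topsis_score,rank
Model21,PCA+FOX-FS+RF,0.9913,0.9882,0.9913,1.0000,1
Model22,PCA+ISOMAP weighted ensemble+RF,0.9825,0.9728,0.9880,0.0000,3
Model23,ISOMAP+FOX-FS+RF,0.9843,0.9818,0.9888,0.4736,2
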