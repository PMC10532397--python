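model,label,accuracy,f2_score,auc_roc,topsis_score,rank
Model21,PCA+FOX-FS+RF,0.9065,0.9201,0.9548,1.0000,1
Model22,PCA+LLE weighted ensemble+RF,0.8924,0.9092,0.9464,0.5508,2
Model23,LLE+FOX-FS+RF,0.8812,0.8965,0.9259,0.0000,3
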