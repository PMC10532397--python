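model,label,accuracy,f2_score,auc_roc,topsis_score,rank
Model1,DeiT+LR,0.6541,0.6142,0.7075,0.0485,15
Model2,DeiT+NB,0.6271,0.6083,0.7292,0.0754,12
Model3,DeiT+SVC,0.7876,0.6874,0.8878,0.4792,7
Model4,DeiT+KNN,0.8076,0.7219,0.908,0.5891,6
Model5,DeiT+RF,0.8712,0.8095,0.9414,0.8764,2
Model6,SwinTransformer+LR,0.6376,0.6217,0.6955,0.0656,13
Model7,SwinTransformer+NB,0.6188,0.6023,0.7252,0.0633,14
Model8,SwinTransformer+SVC,0.8135,0.7402,0.9084,0.6413,5
Model9,SwinTransformer+KNN,0.8624,0.7983,0.937,0.8384,3
Model10,SwinTransformer+RF,0.8835,0.8461,0.9463,1,1
Model11,Mixer-MLP+LR,0.66,0.6513,0.7249,0.1788,11
Model12,Mixer-MLP+NB,0.6594,0.6232,0.8443,0.2964,10
Model13,Mixer-MLP+SVC,0.7889,0.649,0.8961,0.407,9
Model14,Mixer-MLP+KNN,0.7859,0.6641,0.901,0.4417,8
Model15,Mixer-MLP+RF,0.8541,0.7745,0.9296,0.7595,4
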