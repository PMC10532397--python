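model,label,accuracy,f2_score,auc_roc,topsis_score,rank
Model1,DeiT+LR,0.8427,0.8023,0.8929,0.5016,9
Model2,DeiT+NB,0.7138,0.7036,0.8460,0.2536,13
Model3,DeiT+SVC,0.9091,0.9069,0.9590,0.8067,6
Model4,DeiT+KNN,0.7797,0.7302,0.8613,0.3233,12
Model5,DeiT+RF,0.9685,0.9707,0.9884,0.9716,3
Model6,SwinTransformer+LR,0.8899,0.8565,0.9283,0.6622,7
Model7,SwinTransformer+NB,0.7028,0.6901,0.7684,0.0807,15
Model8,SwinTransformer+SVC,0.9231,0.9318,0.9640,0.8621,4
Model9,SwinTransformer+KNN,0.8444,0.8432,0.9014,0.5878,8
Model10,SwinTransformer+RF,0.9790,0.9833,0.9885,1.0000,1
Model11,Mixer-MLP+LR,0.8252,0.7844,0.9019,0.4898,10
Model12,Mixer-MLP+NB,0.7028,0.6537,0.7993,0.0903,14
Model13,Mixer-MLP+SVC,0.9126,0.9170,0.9628,0.8319,5
Model14,Mixer-MLP+KNN,0.7885,0.7555,0.8728,0.3853,11
Model15,Mixer-MLP+RF,0.9455,0.9819,0.9884,0.9968,2
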