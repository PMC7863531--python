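algorithm,metric,low,medium,high,very_high
logistic_regression,precision,0.4171,0.3860,0.3072,0.4536
logistic_regression,recall,0.3852,0.3716,0.4145,0.4213
logistic_regression,f1,0.4005,0.3786,0.3529,0.4369
ann,precision,0.5508,0.4181,0.4155,0.5612
ann,recall,0.5130,0.5146,0.2707,0.5209
ann,f1,0.5312,0.4614,0.3278,0.5403
random_forest,precision,0.6441,0.3068,0.3832,0.7031
random_forest,recall,0.7030,0.5533,0.6197,0.7138
random_forest,f1,0.6723,0.3948,0.4736,0.7084
gradient_boosting,precision,0.6264,0.2254,0.7251,0.7902
gradient_boosting,recall,0.4631,0.5043,0.7188,0.7096
gradient_boosting,f1,0.5325,0.3116,0.7219,0.7477
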