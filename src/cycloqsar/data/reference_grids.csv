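division,model,metric,cell_line,general,drug_like,sigma_printed
diverse,PLS,R2,BxPC-3,0.552,0.494,-0.058
diverse,PLS,R2,NCI-H446,0.659,0.526,-0.133
diverse,PLS,R2,SW1990,0.644,0.585,-0.059
diverse,PLS,R2,NCI-H157,0.527,0.531,0.004
diverse,PLS,Q2,BxPC-3,0.000,0.035,0.035
diverse,PLS,Q2,NCI-H446,0.001,0.026,0.025
diverse,PLS,Q2,SW1990,0.021,0.158,0.137
diverse,PLS,Q2,NCI-H157,0.038,0.106,0.068
diverse,PLS,r2,BxPC-3,0.102,0.307,0.205
diverse,PLS,r2,NCI-H446,0.218,0.025,-0.193
diverse,PLS,r2,SW1990,0.084,0.193,0.109
diverse,PLS,r2,NCI-H157,0.019,0.118,0.099
diverse,SVR,R2,BxPC-3,0.994,0.686,0.308
diverse,SVR,R2,NCI-H446,0.966,0.763,-0.203
diverse,SVR,R2,SW1990,0.993,0.808,-0.185
diverse,SVR,R2,NCI-H157,0.988,0.705,-0.283
diverse,SVR,Q2,BxPC-3,0.994,0.000,-0.994
diverse,SVR,Q2,NCI-H446,0.962,0.002,-0.960
diverse,SVR,Q2,SW1990,0.992,0.069,-0.923
diverse,SVR,Q2,NCI-H157,0.987,0.001,-0.986
diverse,SVR,r2,BxPC-3,0.000,0.396,0.396
diverse,SVR,r2,NCI-H446,0.088,0.110,0.022
diverse,SVR,r2,SW1990,0.025,0.258,0.233
diverse,SVR,r2,NCI-H157,0.023,0.077,0.054
diverse,Bayes,At,BxPC-3,0.883,0.917,0.034
diverse,Bayes,At,NCI-H446,1.000,0.967,-0.033
diverse,Bayes,At,SW1990,0.900,0.933,0.033
diverse,Bayes,At,NCI-H157,0.967,0.933,-0.034
diverse,Bayes,Av,BxPC-3,0.783,0.817,0.034
diverse,Bayes,Av,NCI-H446,0.917,0.917,0.000
diverse,Bayes,Av,SW1990,0.883,0.783,-0.100
diverse,Bayes,Av,NCI-H157,0.867,0.867,0.000
diverse,Bayes,Ap,BxPC-3,0.606,0.576,-0.030
diverse,Bayes,Ap,NCI-H446,0.758,0.879,0.121
diverse,Bayes,Ap,SW1990,0.576,0.667,0.091
diverse,Bayes,Ap,NCI-H157,0.485,0.636,0.151
diverse,SVM,At,BxPC-3,1.000,1.000,0.000
diverse,SVM,At,NCI-H446,1.000,1.000,0.000
diverse,SVM,At,SW1990,1.000,1.000,0.000
diverse,SVM,At,NCI-H157,1.000,1.000,0.000
diverse,SVM,Av,BxPC-3,0.550,0.500,-0.050
diverse,SVM,Av,NCI-H446,0.867,0.817,-0.050
diverse,SVM,Av,SW1990,0.650,0.533,-0.117
diverse,SVM,Av,NCI-H157,0.633,0.617,-0.016
diverse,SVM,Ap,BxPC-3,0.455,0.636,0.181
diverse,SVM,Ap,NCI-H446,0.788,0.879,0.091
diverse,SVM,Ap,SW1990,0.545,0.758,0.213
diverse,SVM,Ap,NCI-H157,0.697,0.636,-0.061
cluster_diverse,PLS,R2,BxPC-3,0.506,0.474,-0.032
cluster_diverse,PLS,R2,NCI-H446,0.593,0.396,-0.197
cluster_diverse,PLS,R2,SW1990,0.542,0.493,-0.049
cluster_diverse,PLS,R2,NCI-H157,0.587,0.542,-0.045
cluster_diverse,PLS,Q2,BxPC-3,0.011,0.007,-0.004
cluster_diverse,PLS,Q2,NCI-H446,0.015,0.019,0.004
cluster_diverse,PLS,Q2,SW1990,0.005,0.002,-0.003
cluster_diverse,PLS,Q2,NCI-H157,0.006,0.040,0.034
cluster_diverse,PLS,r2,BxPC-3,0.178,0.215,0.037
cluster_diverse,PLS,r2,NCI-H446,0.055,0.201,0.146
cluster_diverse,PLS,r2,SW1990,0.000,0.222,0.222
cluster_diverse,PLS,r2,NCI-H157,0.087,0.056,-0.031
cluster_diverse,SVR,R2,BxPC-3,0.997,0.716,-0.281
cluster_diverse,SVR,R2,NCI-H446,0.965,0.756,-0.209
cluster_diverse,SVR,R2,SW1990,0.993,0.839,-0.154
cluster_diverse,SVR,R2,NCI-H157,0.987,0.655,-0.332
cluster_diverse,SVR,Q2,BxPC-3,0.997,0.021,-0.976
cluster_diverse,SVR,Q2,NCI-H446,0.962,0.025,-0.937
cluster_diverse,SVR,Q2,SW1990,0.993,0.124,-0.869
cluster_diverse,SVR,Q2,NCI-H157,0.986,0.019,-0.967
cluster_diverse,SVR,r2,BxPC-3,0.008,0.139,0.131
cluster_diverse,SVR,r2,NCI-H446,0.029,0.001,-0.028
cluster_diverse,SVR,r2,SW1990,0.040,0.075,0.035
cluster_diverse,SVR,r2,NCI-H157,0.019,0.087,0.068
cluster_diverse,Bayes,At,BxPC-3,0.967,0.885,-0.082
cluster_diverse,Bayes,At,NCI-H446,0.951,0.934,-0.017
cluster_diverse,Bayes,At,SW1990,0.934,0.918,-0.016
cluster_diverse,Bayes,At,NCI-H157,0.984,0.885,-0.099
cluster_diverse,Bayes,Av,BxPC-3,0.852,0.803,-0.049
cluster_diverse,Bayes,Av,NCI-H446,0.934,0.918,-0.016
cluster_diverse,Bayes,Av,SW1990,0.852,0.836,-0.016
cluster_diverse,Bayes,Av,NCI-H157,0.820,0.820,0.000
cluster_diverse,Bayes,Ap,BxPC-3,0.656,0.625,-0.031
cluster_diverse,Bayes,Ap,NCI-H446,0.625,0.906,0.281
cluster_diverse,Bayes,Ap,SW1990,0.625,0.656,0.031
cluster_diverse,Bayes,Ap,NCI-H157,0.625,0.625,0.000
cluster_diverse,SVM,At,BxPC-3,1.000,0.984,-0.016
cluster_diverse,SVM,At,NCI-H446,1.000,1.000,0.000
cluster_diverse,SVM,At,SW1990,1.000,1.000,0.000
cluster_diverse,SVM,At,NCI-H157,1.000,0.984,-0.016
cluster_diverse,SVM,Av,BxPC-3,0.505,0.475,-0.030
cluster_diverse,SVM,Av,NCI-H446,0.803,0.852,0.049
cluster_diverse,SVM,Av,SW1990,0.590,0.623,0.033
cluster_diverse,SVM,Av,NCI-H157,0.656,0.623,-0.033
cluster_diverse,SVM,Ap,BxPC-3,0.656,0.719,0.063
cluster_diverse,SVM,Ap,NCI-H446,0.875,0.875,0.000
cluster_diverse,SVM,Ap,SW1990,0.625,0.719,0.094
cluster_diverse,SVM,Ap,NCI-H157,0.688,0.719,0.031
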