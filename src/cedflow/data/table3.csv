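case_id,V_ADC_pre,mean_ADC_pre,V_T2_pre,ratio_pre,V_ADC_post,mean_ADC_post,V_T2_post,ratio_post,dV_ADC,dV_T2,Vi
1,20.2,1148.3,20.1,3.09,25.2,1756.2,23.3,6.1,5.0,3.2,4.0
2,26.3,1057.0,25.8,2.50,31.2,1650.1,29.1,6.8,4.9,3.3,3.8
3,28.0,996.7,27.9,3.19,32.0,1650.0,32.1,6.1,4.0,4.2,4.2
4,16.1,1194.1,16.0,2.38,21.8,1731.9,21.7,7.1,5.7,5.7,5.7
5,17.1,1005.8,16.9,2.64,22.0,1753.3,21.5,6.3,4.9,4.6,5.0
6,19.8,1204.2,19.5,2.50,24.2,1865.4,20.9,5.5,4.4,1.4,4.2
7,15.0,965.7,13.9,2.50,18.9,1475.1,18.9,5.4,3.9,5.0,5.0
8,17.5,1245.1,17.1,2.31,23.2,1834.5,22.7,6.7,5.7,5.5,5.1
9,12.0,1006.0,11.4,2.43,16.0,1749.4,15.1,6.3,4.0,3.7,3.9
10,18.9,1050.2,18.4,2.43,22.1,1647.0,21.9,5.9,3.2,3.5,3.2
11,20.8,1147.6,20.4,2.94,25.6,1836.4,24.1,6.9,4.8,3.7,4.6
12,26.0,1047.1,25.4,2.57,30.5,1843.8,30.0,6.1,4.5,4.6,4.5
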