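artery,cross_section,layer,c1_kPa,c2_kPa,c3_kPa,nmse_percent
1,1,intima,0.10,0.04,0.15,1.61
1,1,wall,6.17,0.04,298.93,1.61
1,2,intima,0.11,0.29,0.47,2.15
1,2,wall,15.04,4.39,237.01,2.15
2,3,intima,6.64,0.11,0.15,6.62
2,3,wall,7.40,-5.60,187.62,6.62
3,4,intima,2.03,57.42,1.56,9.56
3,4,wall,24.92,-141.80,467.32,9.56
4,5,intima,0.66,4.12,0.12,23.01
4,5,wall,14.11,-1.63,38.39,23.01
4,6,intima,3.93,-0.59,3.76,6.85
4,6,wall,5.62,-0.59,103.36,6.85
4,7,intima,0.33,1.10,0.19,17.74
4,7,wall,0.10,112.57,193.34,17.74
4,8,intima,13.12,-5.86,7.42,8.73
4,8,wall,2.03,-3.52,7.42,8.73
5,9,intima,0.10,0.60,0.26,6.98
5,9,wall,0.80,0.05,674.04,6.98
5,10,intima,18.99,-96.68,289.37,21.60
5,10,wall,0.42,0.59,2.30,21.60
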