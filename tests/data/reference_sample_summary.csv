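sample,n_per_area_mean,n_per_area_sd,n_per_area_letters,af_mean_cm2_mean,af_mean_cm2_sd,af_mean_cm2_letters,af_max_cm2_mean,af_max_cm2_sd,af_max_cm2_letters,rf_mean_mean,rf_mean_sd,rf_mean_letters,rf_max_mean,rf_max_sd,rf_max_letters,vfc_pct_mean,vfc_pct_sd,vfc_pct_letters
A,1.44,0.2,cd,0.085,0.01,ab,0.81,0.5,ab,1.50,0.5,a,6.16,1.7,bc,11.84,1.2,b
B,1.10,0.2,a,0.133,0.02,fg,0.75,0.2,a,1.79,0.3,b,4.41,1.1,ab,11.37,1.1,b
C,0.99,0.2,a,0.124,0.02,e,1.25,0.0,bc,2.03,0.3,c,4.77,0.7,ab,14.30,0.9,cd
D,1.19,0.1,ab,0.084,0.01,a,0.83,0.4,ab,1.72,0.0,a,3.89,0.3,a,8.74,1.0,a
E,1.42,0.2,c,0.083,0.00,a,0.69,0.0,a,1.90,0.1,b,4.75,0.5,ab,11.56,1.5,b
F,1.30,0.1,b,0.135,0.03,fg,1.19,0.4,bc,1.92,0.0,bc,4.73,0.2,ab,15.64,1.0,d
G,1.38,0.2,c,0.122,0.02,ef,1.01,0.5,b,1.93,0.1,bc,4.48,0.5,ab,14.11,1.1,cd
H,1.54,0.6,d,0.089,0.01,b,1.19,0.3,bc,2.08,0.1,c,7.90,0.1,d,11.33,0.2,b
I,1.76,0.2,e,0.075,0.01,a,0.90,0.3,ab,2.00,0.1,c,6.41,0.0,c,13.05,2.1,bc
J,1.14,0.2,ab,0.099,0.01,bc,0.68,0.2,a,1.86,0.2,b,4.91,1.4,b,9.75,0.6,a
K,1.41,0.2,c,0.112,0.01,cd,1.60,0.2,d,2.05,0.1,c,6.18,0.5,bc,15.60,1.5,d
L,1.45,0.4,cd,0.085,0.01,ab,0.82,0.2,ab,1.89,0.1,b,5.53,1.3,b,12.03,0.8,b
M,1.40,0.2,c,0.123,0.01,ef,0.91,0.1,ab,1.97,0.1,c,5.22,0.3,b,15.33,1.8,d
N,1.29,0.1,b,0.118,0.03,de,1.03,0.2,b,2.06,0.1,c,5.71,1.2,bc,14.44,0.7,cd
O,1.87,0.2,e,0.138,0.01,g,1.33,0.3,c,2.05,0.1,c,6.32,1.1,c,18.52,0.3,e
P,1.68,0.4,de,0.095,0.01,c,1.20,0.3,bc,2.08,0.1,c,7.91,0.1,d,14.46,1.6,cd
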