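subject,sex,age_years,body_mass_kg,height_m,bmi_reported,sat_mm,career_years,practice_h_wk
1,M,15,50,1.76,16.14,4.6,5,11
2,M,61,78,1.74,25.76,7.0,50,7
3,M,16,70,1.93,18.79,7.1,11,7
4,F,15,60,1.70,20.76,11.1,8,14
5,F,26,74,1.68,26.22,7.5,20,14
6,M,37,70,1.87,20.02,12.6,15,14
7,F,17,60,1.60,23.44,10.4,8,12
8,F,20,55,1.70,19.03,10.8,12,14
9,M,19,50,1.70,17.30,6.0,8,7
10,M,27,69,1.75,22.53,11.0,15,34
11,F,17,52,1.65,19.10,7.2,13,11
12,F,15,48,1.58,19.23,7.5,5,11
13,F,21,40,1.60,17.30,8.3,15,18
14,F,25,55,1.65,22.53,8.4,16,18
15,F,24,57,1.69,19.10,9.2,20,21
16,M,28,58,1.68,20.55,9.3,17,32
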