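animal_id,map_nr,chamber,heart_rate,n_points,volume_ml,n_circles,circles_lateral,circles_septal,circles_posterior,circles_anterior,circles_superior
1,1,RA,115,6839,77.65,184,30,23,26,,9
1,4,RA,115,6907,77.65,184,30,23,26,,9
1,5,LV,122,4806,53.16,122,10,14,20,21,
1,9,LV,130,4726,53.16,122,10,14,20,21,
2,10,RA,120,7475,69.66,167,21,17,16,,11
2,12,RA,134,7475,69.66,167,21,17,16,,11
2,14,LV,120,5060,50.10,129,11,13,26,24,
2,16,LV,86,5060,50.10,129,11,13,26,24,
2,18,LA,86,4835,39.95,100,11,10,16,12,15
2,20,LA,90,4964,40.68,100,11,10,16,12,15
2,21,RV,104,6440,68.88,138,12,16,17,21,
2,23,RV,95,6445,68.64,138,12,16,17,21,
3,25,RA,130,7815,81.00,193,30,35,33,,10
3,26,RV,135,3547,33.95,74,9,13,9,14,
3,32,RV,150,4698,35.82,66,10,9,6,6,
5,36,RA,95,6848,64.54,176,41,21,21,,13
5,37,RV,110,3158,25.93,84,12,15,16,9,
5,39,RA,145,6799,69.00,186,45,32,26,,24
5,42,RV,132,3420,28.04,84,12,15,16,9,
5,44,LA,145,5481,40.70,105,4,9,10,9,11
5,45,LA,171,5481,40.70,105,4,9,10,9,11
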