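catchment_id,county,watershed_area_ha,easement_area_ha,wq_wetland_area_ha,wq_wetland_watershed_pct,non_depressional_corn_soy_pct,depressional_corn_soy_pct,total_depressional_area_pct,existing_wetland_area_pct
1,Emmet,322,7,3,0.9,82,9,9,0.6
2,Emmet,287,17,3,0.9,65,19,20,3.6
3,Emmet,250,16,4,1.7,83,3,4,0.9
4,Emmet,498,22,9,1.7,60,0,1,6.7
5,Emmet,184,15,6,3.4,86,3,3,2.1
6,Hancock/Kossuth,1144,16,4,0.4,79,9,9,1.2
7,Kossuth,664,12,8,1.2,76,16,17,2.1
8,Kossuth,732,18,6,0.8,79,14,15,0.5
9,Winnebago,448,11,6,1.3,80,5,5,3.6
10,Winnebago,527,40,13,2.5,72,17,17,2.8
11,Winnebago,242,8,3,1.1,77,2,3,4.2
12,Pocahontas,945,42,7,0.7,84,11,11,0.5
13,Calhoun,651,24,8,1.2,87,8,8,0.5
14,Calhoun,233,9,2,0.9,87,10,10,0.2
15,Humboldt,608,12,3,0.5,81,5,5,2.0
16,Humboldt,432,12,2,0.4,94,2,2,0.8
17,Webster,560,11,2,0.4,83,13,13,0.1
18,Webster,372,11,3,0.7,86,8,8,0.6
19,Wright,560,42,18,3.2,81,6,6,5.0
20,Hamilton,1219,35,15,1.2,75,16,17,0.5
21,Hamilton,388,20,10,2.6,84,3,3,5.8
22,Greene,290,13,4,1.5,92,1,1,0.1
23,Greene,284,15,5,1.6,75,0,0,1.4
24,Greene,281,6,1,0.5,84,8,8,0.4
25,Greene,407,11,3,0.7,90,5,5,0.4
26,Greene/Calhoun,854,18,7,0.8,91,3,3,0.9
27,Boone/Hamilton,1296,26,11,0.9,62,4,4,4.4
28,Boone,328,7,2,0.6,87,8,8,0.5
29,Boone,260,17,4,1.7,93,3,3,0.4
30,Boone,129,25,8,6.4,87,8,8,0.6
31,Story,349,15,4,1.1,91,2,2,0.5
32,Story,531,14,7,1.4,81,10,10,0.7
33,Dallas,274,8,2,0.8,51,1,2,1.7
34,Dallas,593,12,3,0.5,61,5,6,1.2
35,Dallas,508,23,7,1.4,72,8,8,0.4
36,Polk,936,18,7,0.8,85,1,1,0.6
37,Polk,241,9,2,1.0,88,4,4,0.2
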