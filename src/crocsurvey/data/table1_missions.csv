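mission_id,time_window,distance_km,flight_min,surface_km2,photo_count,count_gharial,count_mugger
1,11:00-12:00,35.2,41,3.49,1589,2,0
2,12:00-13:00,26.6,31,1.53,690,0,9
3,14:00-15:00,28.3,33,3.33,1529,3,1
4,15:00-16:00,35.2,41,1.94,850,1,13
5,16:00-17:00,24.0,28,1.04,512,8,5
6,11:00-12:00,30.0,35,2.47,1304,9,1
7,12:00-13:00,30.0,35,1.66,818,10,9
8,14:00-15:00,33.5,39,1.92,929,22,10
9,14:00-15:00,12.9,15,1.29,631,0,1
10,15:00-16:00,35.2,41,2.33,1180,10,8
11,11:00-12:00,8.6,10,1.01,1081,2,2
12,11:00-12:00,15.4,18,0.62,308,10,8
13,12:00-13:00,33.5,39,1.78,857,3,0
14,14:00-15:00,12.0,14,0.45,784,5,2
15,15:00-16:00,29.2,34,1.16,570,32,9
16,15:00-16:00,24.0,28,0.89,440,22,4
17,11:00-12:00,36.0,42,4.51,2102,26,0
18,12:00-13:00,34.3,40,3.87,1778,20,0
19,14:00-15:00,27.5,32,1.33,1675,2,0
20,15:00-16:00,21.5,25,1.19,579,0,2
21,16:00-17:00,12.0,14,0.44,458,1,1
22,16:00-17:00,18.0,21,0.64,293,3,1
23,17:00-18:00,20.6,24,0.92,423,13,4
24,12:00-13:00,33.5,39,1.41,717,0,0
25,13:00-14:00,21.5,25,1.98,962,0,0
26,16:00-17:00,21.5,25,1.00,489,0,0
27,12:00-13:00,32.6,29,0.49,581,1,28
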