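item,kind,route,y2017,y2018,y2019,y2020,printed_average,printed_rate_pct
All notifiable diseases,all_cases,,145986,191084,189752,92955,175607,-47.1
All notifiable diseases,all_ndoi,,0.508,0.599,0.597,0.269,,-52.6
Direct-contact route,route_ndoi,direct-contact,0.384,0.557,0.344,0.221,0.428,-48.5
Direct-contact route,route_cases,direct-contact,44671,69950,41251,18319,51957,-64.7
Hand-foot-and-mouth disease (HFMD),disease,direct-contact,24292,52976,24788,5619,34019,-83.5
Syphilis,disease,direct-contact,13932,12447,12637,9721,13005,-25.3
Gonorrhoea,disease,direct-contact,5836,3908,3188,2540,4311,-41.1
Acquired immune deficiency syndrome (AIDS),disease,direct-contact,555,546,562,423,554,-23.7
Measles,disease,direct-contact,49,57,71,10,59,-83.1
Brucellosis,disease,direct-contact,4,8,2,4,5,-14.3
Leprosy,disease,direct-contact,1,2,2,2,2,20.0
Rabies,disease,direct-contact,2,5,0,0,2,-100.0
Hydatid disease (HD),disease,direct-contact,0,1,1,0,1,-100.0
Water-food route,route_ndoi,water-food,0.578,0.458,0.485,0.231,0.507,-54.4
Water-food route,route_cases,water-food,9038,7855,7840,3858,8244,-53.2
Infectious diarrhea (ID),disease,water-food,6627,5661,5961,2804,6083,-53.9
Hepatitis A,disease,water-food,302,272,401,224,325,-31.1
Hepatitis B,disease,water-food,919,970,940,542,943,-42.5
Hepatitis C,disease,water-food,615,479,243,172,446,-61.4
Hepatitis D,disease,water-food,336,325,150,39,270,-85.6
Hepatitis E,disease,water-food,96,74,75,32,82,-60.8
Hepatitis (unspecified),disease,water-food,94,44,35,20,58,-65.3
Bacillary and amoebic dysentery (BAD),disease,water-food,0,2,1,1,1,0.0
Typhoid and paratyphoid (TP),disease,water-food,30,15,18,16,21,-23.8
Acute hemorrhagic conjunctivitis (AHC),disease,water-food,19,13,16,8,16,-50.0
Airborne route,route_ndoi,airborne,0.255,0.313,0.434,0.174,0.334,-47.9
Airborne route,route_cases,airborne,19120,17568,45583,24701,27424,-9.9
Influenza,disease,airborne,6144,4201,33115,15706,14487,8.4
Pulmonary tuberculosis (PT),disease,airborne,6435,6516,6223,5869,6391,-8.2
Scarlatina,disease,airborne,4234,4423,3726,812,4128,-80.3
Mumps,disease,airborne,2209,2290,2098,1216,2199,-44.7
Pertussis,disease,airborne,84,112,149,9,115,-92.2
Rubella,disease,airborne,4,21,265,15,97,-84.5
Epidemic hemorrhagic fever (EHF),disease,airborne,5,2,2,2,3,-33.3
Epidemic cerebrospinal meningitis (ECM),disease,airborne,1,3,5,0,3,-100.0
Human infection with H7N9 bird flu (H7N9),disease,airborne,4,0,0,0,1,-100.0
Vector-borne route,route_ndoi,vector-borne,0.413,0.399,0.530,0.268,0.447,-40.0
Vector-borne route,route_cases,vector-borne,63,63,132,31,86,-64.0
Malaria,disease,vector-borne,42,26,25,18,31,-41.9
Dengue,disease,vector-borne,20,36,106,11,54,-79.6
Epidemic encephalitis B (EEB),disease,vector-borne,1,1,1,1,1,0.0
Kala-azar,disease,vector-borne,0,0,0,1,0,NA
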