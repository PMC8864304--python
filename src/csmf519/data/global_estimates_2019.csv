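group,cause,deaths
all,road_traffic,115843
all,neoplasms,95401
all,malaria,81516
all,drowning,77460
all,diarrhoea,72679
all,tuberculosis,70829
all,self_harm,61903
all,lri,58883
all,digestive,56323
all,interpersonal_violence,53540
all,cardiovascular,38634
all,hiv,33527
all,measles,21759
all,collective_violence,21034
all,congenital,17555
all,maternal,12167
all,natural_disasters,992
all,other_cmpn,218570
all,other_ncd,215965
all,other_injuries,155631
all,all_cause,1480227
5-9,diarrhoea,51630
5-9,malaria,49934
5-9,lri,33851
5-9,drowning,33086
5-9,neoplasms,28449
5-9,road_traffic,27989
5-9,tuberculosis,22369
5-9,measles,21764
5-9,congenital,17556
5-9,digestive,16124
5-9,hiv,8349
5-9,collective_violence,5082
5-9,natural_disasters,331
5-9,other_cmpn,86965
5-9,other_ncd,67718
5-9,other_injuries,45778
5-9,all_cause,516971
10-14,malaria,31587
10-14,neoplasms,26820
10-14,lri,25034
10-14,drowning,23610
10-14,road_traffic,22542
10-14,diarrhoea,21047
10-14,hiv,12068
10-14,digestive,10595
10-14,tuberculosis,7823
10-14,collective_violence,5835
10-14,natural_disasters,298
10-14,other_cmpn,61919
10-14,other_ncd,58396
10-14,other_injuries,60572
10-14,all_cause,368151
15-19f,self_harm,32646
15-19f,neoplasms,18298
15-19f,cardiovascular,16953
15-19f,road_traffic,16559
15-19f,tuberculosis,15369
15-19f,digestive,12937
15-19f,maternal,12161
15-19f,interpersonal_violence,10437
15-19f,hiv,5949
15-19f,drowning,4531
15-19f,collective_violence,3315
15-19f,natural_disasters,129
15-19f,other_cmpn,28460
15-19f,other_ncd,47105
15-19f,other_injuries,18373
15-19f,all_cause,243225
15-19m,road_traffic,48757
15-19m,interpersonal_violence,43102
15-19m,self_harm,29255
15-19m,tuberculosis,25265
15-19m,neoplasms,21834
15-19m,cardiovascular,21686
15-19m,digestive,16665
15-19m,drowning,16239
15-19m,hiv,7154
15-19m,collective_violence,6795
15-19m,natural_disasters,232
15-19m,other_cmpn,41237
15-19m,other_ncd,42747
15-19m,other_injuries,30913
15-19m,all_cause,351881
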