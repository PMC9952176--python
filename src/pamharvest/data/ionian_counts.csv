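island,site,stratum,year,detected_gunshots
Zakynthos,Keri,zakynthos_south_coast,2019,3603
Zakynthos,Vasilikos,zakynthos_south_coast,2019,3687
Zakynthos,Keri,zakynthos_south_coast,2020,6735
Zakynthos,Vasilikos,zakynthos_south_coast,2020,8845
Zakynthos,Keri,zakynthos_south_coast,2021,6651
Zakynthos,Vasilikos,zakynthos_south_coast,2021,7361
Zakynthos,Alikanas,zakynthos_inland,2021,919
Zakynthos,Kalipado,zakynthos_inland,2021,1196
Paxi,Kastanida,paxi,2021,1092
Paxi,Ozias,paxi,2021,384
Mathraki,Mathraki,mathraki,2021,711
Othoni,Othoni,othoni,2021,240
Antipaxi,Antipaxi,antipaxi,2021,2351
Corfu,Lefkimi,lefkimi,2021,0
Zakynthos,Keri,zakynthos_south_coast,2022,3647
Zakynthos,Vasilikos,zakynthos_south_coast,2022,3223
Zakynthos,Alikanas,zakynthos_inland,2022,1680
Paxi,Kastanida,paxi,2022,408
Paxi,Ozias,paxi,2022,188
Mathraki,Mathraki,mathraki,2022,2
Othoni,Othoni,othoni,2022,37
Antipaxi,Antipaxi,antipaxi,2022,1054
Corfu,Lefkimi,lefkimi,2022,0
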