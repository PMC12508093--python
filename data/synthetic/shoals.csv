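shoal_id,location_id,observer_id,Sarpa_salpa,Sparisoma_cretense,Siganus_luridus,Siganus_rivulatus
sim001,loc1,obs1,0,0,0,3
sim002,loc2,obs2,3,4,4,2
sim003,loc3,obs3,4,0,0,0
sim004,loc4,obs1,1,4,2,3
sim005,loc5,obs2,0,0,4,0
sim006,loc6,obs3,0,0,7,0
sim007,loc7,obs1,1,0,7,4
sim008,loc1,obs2,0,0,10,0
sim009,loc2,obs3,0,0,0,2
sim010,loc3,obs1,2,0,0,0
sim011,loc4,obs2,0,0,3,4
sim012,loc5,obs3,0,0,0,7
sim013,loc6,obs1,0,0,7,0
sim014,loc7,obs2,0,0,8,4
sim015,loc1,obs3,0,0,5,0
sim016,loc2,obs1,0,0,5,0
sim017,loc3,obs2,5,0,0,0
sim018,loc4,obs3,0,0,2,0
sim019,loc5,obs1,0,22,0,0
sim020,loc6,obs2,0,3,0,0
sim021,loc7,obs3,0,0,1,4
sim022,loc1,obs1,0,4,0,0
sim023,loc2,obs2,0,0,0,2
sim024,loc3,obs3,4,1,4,4
sim025,loc4,obs1,4,5,2,1
sim026,loc5,obs2,0,1,0,5
sim027,loc6,obs3,0,0,0,6
sim028,loc7,obs1,0,2,0,0
sim029,loc1,obs2,0,7,0,0
sim030,loc2,obs3,1,4,2,3
sim031,loc3,obs1,0,0,0,4
sim032,loc4,obs2,6,0,0,0
sim033,loc5,obs3,0,0,0,20
sim034,loc6,obs1,0,0,3,3
sim035,loc7,obs2,0,0,0,6
sim036,loc1,obs3,0,3,1,3
sim037,loc2,obs1,3,0,0,0
sim038,loc3,obs2,0,0,0,17
sim039,loc4,obs3,0,0,7,0
sim040,loc5,obs1,5,0,0,0
sim041,loc6,obs2,9,0,7,0
sim042,loc7,obs3,4,0,5,12
sim043,loc1,obs1,0,0,0,6
sim044,loc2,obs2,0,4,0,0
sim045,loc3,obs3,1,0,1,2
sim046,loc4,obs1,0,0,0,16
sim047,loc5,obs2,0,0,0,7
sim048,loc6,obs3,0,0,1,4
sim049,loc7,obs1,3,0,0,0
sim050,loc1,obs2,3,0,3,2
sim051,loc2,obs3,3,0,0,5
sim052,loc3,obs1,0,0,7,5
sim053,loc4,obs2,0,4,0,0
sim054,loc5,obs3,5,5,2,0
sim055,loc6,obs1,0,4,0,0
sim056,loc7,obs2,5,0,0,0
sim057,loc1,obs3,8,0,8,8
sim058,loc2,obs1,2,0,1,2
sim059,loc3,obs2,2,0,4,1
sim060,loc4,obs3,0,0,7,0
sim061,loc5,obs1,0,3,0,0
sim062,loc6,obs2,3,0,0,0
sim063,loc7,obs3,7,0,8,0
sim064,loc1,obs1,0,2,0,1
sim065,loc2,obs2,5,0,2,5
sim066,loc3,obs3,0,0,12,0
sim067,loc4,obs1,0,2,0,0
sim068,loc5,obs2,3,2,0,0
sim069,loc6,obs3,4,5,4,0
sim070,loc7,obs1,2,3,3,1
sim071,loc1,obs2,2,0,0,0
sim072,loc2,obs3,0,0,9,0
sim073,loc3,obs1,0,3,3,8
sim074,loc4,obs2,0,0,5,0
sim075,loc5,obs3,0,0,0,16
sim076,loc6,obs1,2,0,0,0
sim077,loc7,obs2,3,0,0,1
sim078,loc1,obs3,0,7,4,6
sim079,loc2,obs1,4,0,2,4
sim080,loc3,obs2,5,0,6,5
sim081,loc4,obs3,7,0,1,0
sim082,loc5,obs1,0,6,0,0
sim083,loc6,obs2,0,0,3,1
sim084,loc7,obs3,0,6,0,0
sim085,loc1,obs1,2,0,5,1
sim086,loc2,obs2,2,0,0,0
sim087,loc3,obs3,3,0,4,3
sim088,loc4,obs1,0,6,0,0
sim089,loc5,obs2,0,0,3,0
sim090,loc6,obs3,0,0,5,0
sim091,loc7,obs1,3,0,0,4
sim092,loc1,obs2,0,2,0,0
sim093,loc2,obs3,0,0,10,0
sim094,loc3,obs1,7,0,0,0
sim095,loc4,obs2,0,5,0,0
sim096,loc5,obs3,0,0,14,0
sim097,loc6,obs1,2,0,0,0
sim098,loc7,obs2,0,0,0,2
sim099,loc1,obs3,0,0,11,0
sim100,loc2,obs1,0,3,0,1
sim101,loc3,obs2,2,0,2,0
sim102,loc4,obs3,0,0,12,0
sim103,loc5,obs1,2,0,2,2
sim104,loc6,obs2,0,0,0,6
sim105,loc7,obs3,3,4,0,2
sim106,loc1,obs1,0,0,8,0
sim107,loc2,obs2,0,0,0,6
sim108,loc3,obs3,0,7,0,0
sim109,loc4,obs1,2,1,1,2
sim110,loc5,obs2,0,3,0,0
sim111,loc6,obs3,0,10,0,0
sim112,loc7,obs1,4,0,0,0
sim113,loc1,obs2,0,4,0,0
sim114,loc2,obs3,0,0,3,2
sim115,loc3,obs1,0,4,5,0
sim116,loc4,obs2,2,0,0,0
sim117,loc5,obs3,0,0,5,0
sim118,loc6,obs1,0,0,5,0
sim119,loc7,obs2,7,0,0,10
sim120,loc1,obs3,0,0,12,0
sim121,loc2,obs1,0,0,0,9
sim122,loc3,obs2,3,0,2,2
sim123,loc4,obs3,0,16,0,16
sim124,loc5,obs1,0,0,6,0
sim125,loc6,obs2,0,0,7,0
sim126,loc7,obs3,0,0,5,0
sim127,loc1,obs1,3,0,0,0
sim128,loc2,obs2,0,4,0,0
sim129,loc3,obs3,0,0,8,0
sim130,loc4,obs1,0,0,21,0
sim131,loc5,obs2,0,0,7,0
sim132,loc6,obs3,0,0,0,16
sim133,loc7,obs1,8,5,7,6
sim134,loc1,obs2,0,0,2,3
sim135,loc2,obs3,0,0,4,3
sim136,loc3,obs1,0,0,4,2
sim137,loc4,obs2,0,0,0,9
sim138,loc5,obs3,0,2,1,2
sim139,loc6,obs1,5,0,0,6
sim140,loc7,obs2,0,0,0,8
sim141,loc1,obs3,5,0,0,0
sim142,loc2,obs1,0,0,0,10
sim143,loc3,obs2,0,3,0,0
sim144,loc4,obs3,4,0,0,0
sim145,loc5,obs1,0,0,0,10
sim146,loc6,obs2,0,0,7,6
sim147,loc7,obs3,0,0,32,0
sim148,loc1,obs1,0,0,3,4
sim149,loc2,obs2,0,0,0,15
sim150,loc3,obs3,4,0,0,0
sim151,loc4,obs1,2,1,1,2
sim152,loc5,obs2,0,0,8,0
sim153,loc6,obs3,0,0,8,0
sim154,loc7,obs1,1,0,4,2
sim155,loc1,obs2,3,0,0,0
sim156,loc2,obs3,0,0,3,5
sim157,loc3,obs1,0,2,0,0
sim158,loc4,obs2,0,0,26,0
sim159,loc5,obs3,0,2,0,0
sim160,loc6,obs1,1,0,2,2
sim161,loc7,obs2,0,0,4,0
sim162,loc1,obs3,3,2,5,3
sim163,loc2,obs1,0,0,0,5
sim164,loc3,obs2,12,0,0,13
sim165,loc4,obs3,0,0,0,4
sim166,loc5,obs1,0,0,6,0
sim167,loc6,obs2,0,0,11,0
sim168,loc7,obs3,2,3,3,2
sim169,loc1,obs1,0,5,0,0
sim170,loc2,obs2,1,1,1,1
sim171,loc3,obs3,0,0,10,8
sim172,loc4,obs1,0,0,4,0
sim173,loc5,obs2,4,0,5,0
sim174,loc6,obs3,0,0,3,0
sim175,loc7,obs1,0,0,2,0
sim176,loc1,obs2,0,0,0,3
sim177,loc2,obs3,3,0,0,0
sim178,loc3,obs1,0,0,0,5
sim179,loc4,obs2,5,2,3,3
sim180,loc5,obs3,0,0,22,0
sim181,loc6,obs1,0,0,8,6
sim182,loc7,obs2,0,0,7,0
sim183,loc1,obs3,0,7,0,0
sim184,loc2,obs1,0,1,3,1
sim185,loc3,obs2,4,0,0,0
sim186,loc4,obs3,0,0,14,0
sim187,loc5,obs1,2,3,4,3
sim188,loc6,obs2,0,2,0,0
sim189,loc7,obs3,1,0,1,4
sim190,loc1,obs1,0,0,0,12
sim191,loc2,obs2,9,5,0,6
sim192,loc3,obs3,0,0,0,7
sim193,loc4,obs1,0,0,8,0
sim194,loc5,obs2,0,0,2,3
sim195,loc6,obs3,7,0,0,0
sim196,loc7,obs1,0,0,12,0
sim197,loc1,obs2,0,0,5,0
sim198,loc2,obs3,0,0,7,0
sim199,loc3,obs1,4,0,0,0
sim200,loc4,obs2,0,11,0,0
sim201,loc5,obs3,0,0,0,8
sim202,loc6,obs1,0,0,2,0
sim203,loc7,obs2,0,0,4,5
sim204,loc1,obs3,0,0,0,11
sim205,loc2,obs1,6,0,7,2
sim206,loc3,obs2,0,0,1,1
sim207,loc4,obs3,0,0,0,3
sim208,loc5,obs1,0,0,6,0
sim209,loc6,obs2,0,0,7,1
sim210,loc7,obs3,0,3,0,0
sim211,loc1,obs1,7,0,0,0
sim212,loc2,obs2,3,2,1,2
sim213,loc3,obs3,0,0,0,2
sim214,loc4,obs1,0,0,2,2
sim215,loc5,obs2,0,0,0,2
sim216,loc6,obs3,0,0,0,6
sim217,loc7,obs1,3,0,0,0
sim218,loc1,obs2,0,2,0,0
sim219,loc2,obs3,1,0,0,3
sim220,loc3,obs1,0,0,0,5
sim221,loc4,obs2,0,8,0,0
sim222,loc5,obs3,2,2,3,4
sim223,loc6,obs1,11,0,0,0
sim224,loc7,obs2,0,0,0,9
sim225,loc1,obs3,5,0,0,0
sim226,loc2,obs1,0,13,0,14
sim227,loc3,obs2,0,3,0,0
sim228,loc4,obs3,2,0,0,0
sim229,loc5,obs1,3,0,0,0
sim230,loc6,obs2,0,13,0,0
sim231,loc7,obs3,0,2,0,0
sim232,loc1,obs1,0,0,0,7
sim233,loc2,obs2,0,0,3,0
sim234,loc3,obs3,1,4,2,3
sim235,loc4,obs1,5,3,2,4
sim236,loc5,obs2,0,0,3,3
sim237,loc6,obs3,3,0,0,2
sim238,loc7,obs1,2,0,1,4
sim239,loc1,obs2,3,1,3,1
sim240,loc2,obs3,2,0,0,0
sim241,loc3,obs1,3,0,0,0
sim242,loc4,obs2,0,0,12,0
sim243,loc5,obs3,2,0,0,0
sim244,loc6,obs1,0,0,0,5
sim245,loc7,obs2,0,3,0,0
sim246,loc1,obs3,0,6,0,0
sim247,loc2,obs1,0,0,8,0
sim248,loc3,obs2,5,0,0,0
sim249,loc4,obs3,0,0,4,6
sim250,loc5,obs1,9,0,9,0
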