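type_id,name,group,start_density,final_density,death_threshold_D,death_threshold_FD,death_threshold_FDM,migration_threshold_FDM
0,on-off_dsgca,on-off,357,125,2.0367,2.0334,2.023,2.02
1,on-off_dsgcb,on-off,357,125,2.0367,2.0334,2.023,2.02
2,on-off_dsgcc,on-off,357,125,2.0367,2.0334,2.023,2.02
3,on-off_dsgcd,on-off,357,125,2.0367,2.0334,2.023,2.02
4,on-off_m,on-off,57,20,1.9872,1.9855,1.9855,1.983
5,on-off_led,on-off,714,250,2.116,2.098,2.08,2.065
6,on-off_u,on-off,57,20,1.9872,1.9855,1.985,1.983
7,on-off_v,on-off,57,20,1.9872,1.9855,1.985,1.983
8,on-off_w,on-off,171,60,2.001,1.9978,1.996,1.994
9,on-off_x,on-off,143,50,1.9968,1.9945,1.994,1.9925
10,on-off_y,on-off,114,40,1.994,1.993,1.993,1.991
11,on-off_z,on-off,114,40,1.994,1.993,1.993,1.991
100,on_dsgca,on,114,40,1.994,1.993,1.993,1.991
101,on_dsgcb,on,114,40,1.994,1.993,1.993,1.991
102,on_dsgcc,on,114,40,1.994,1.993,1.993,1.991
103,on_aplha,on,114,40,1.994,1.993,1.993,1.991
104,on_m2,on,160,56,2.0,1.9953,1.994,1.992
105,on_m4,on,57,20,1.9872,1.9855,1.985,1.983
106,on_m5,on,57,20,1.9872,1.9855,1.985,1.983
107,on_o,on,428,150,2.05,2.0425,2.035,2.031
108,on_p,on,286,100,2.022,2.018,2.012,2.01
109,on_q,on,286,100,2.022,2.018,2.012,2.01
110,on_r,on,228,80,2.011,2.0082,2.004,2.002
111,on_s,on,171,60,2.001,1.9978,1.995,1.993
112,on_t,on,171,60,2.001,1.9978,1.995,1.993
113,on_u,on,143,50,1.9968,1.9945,1.994,1.9925
114,on_v,on,143,50,1.9968,1.9945,1.994,1.9925
115,on_w,on,97,34,1.993,1.9934,1.989,1.987
116,on_x,on,57,20,1.9872,1.9855,1.985,1.983
117,on_y,on,57,20,1.9872,1.9855,1.985,1.983
118,on_z,on,57,20,1.9872,1.9855,1.985,1.983
200,off_aplhaa,off,114,40,1.994,1.993,1.993,1.991
201,off_aplhab,off,114,40,1.994,1.993,1.993,1.991
202,off_m1,off,180,63,2.006,1.9979,1.998,1.996
203,off_j,off,571,200,2.078,2.065,2.058,2.049
204,off_mini_j,off,1000,350,2.179,2.155,2.134,2.098
205,off_midi_j,off,228,80,2.011,2.0082,2.004,2.002
206,off_u,off,57,20,1.9872,1.9855,1.985,1.983
207,off_v,off,57,20,1.9872,1.9855,1.985,1.983
208,off_w,off,171,60,2.001,1.9978,1.995,1.993
209,off_x,off,143,50,1.9968,1.9945,1.994,1.9925
210,off_y,off,114,40,1.994,1.993,1.993,1.991
211,off_z,off,106,37,1.9935,1.9928,1.989,1.988
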