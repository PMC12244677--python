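# SYNTHETIC reconstruction of per-study reflex observations.
# Generated by armloop.fixtures.reconstruct_precursor_observations;
# constructed so the estimation pipeline reproduces the packaged gain matrix exactly.
# PSTH rows carry integer motor-unit counts; EMG-A rows carry p (fractional activity
# increase), b (background activity, MVC fraction), s (stimulus, fraction of motor threshold).
method,source,target,n_plus,n_minus,n_tot,p,b,s
psth_nerve,ECR+ECU,Delt Post,182.0,0.0,1000.0,,,
psth_nerve,ECR+ECU,Bi,0.0,116.0,1000.0,,,
psth_nerve,ECR+ECU,Tri,380.0,0.0,1000.0,,,
psth_nerve,Bi+Bra,Tri,0.0,420.0,1000.0,,,
psth_nerve,Bi+Bra,Bi,140.0,0.0,1000.0,,,
psth_nerve,Bi,Bi,500.0,0.0,1000.0,,,
psth_nerve,Bi,Tri,0.0,190.0,1000.0,,,
psth_nerve,Delt Ant,Delt Ant,230.0,0.0,1000.0,,,
psth_nerve,Delt Post,Bi,0.0,3.0,1000.0,,,
psth_nerve,Bi,Delt Post,8.0,0.0,1000.0,,,
psth_nerve,Tri,Delt Post,5.0,0.0,1000.0,,,
psth_nerve,Brd,Delt Post,91.0,0.0,1000.0,,,
psth_nerve,PT,Tri,0.0,200.0,1000.0,,,
psth_nerve,ECR,FCR,0.0,470.0,1000.0,,,
psth_nerve,FCR,ECR,0.0,460.0,1000.0,,,
psth_tap,Delt Ant,Bi,360.0,0.0,2000.0,,,
psth_tap,Delt Post,Tri,13.0,0.0,2000.0,,,
psth_tap,Bi,Pec,24.0,0.0,2000.0,,,
psth_tap,Tri,Pec,5.0,0.0,2000.0,,,
psth_tap,Brd,Bi,0.0,420.0,2000.0,,,
psth_tap,PT,Brd,310.0,0.0,2000.0,,,
psth_tap,ECU,ECR,1240.0,0.0,2000.0,,,
psth_tap,FCR,FCR,1200.0,0.0,2000.0,,,
psth_tap,FCU,FCR,1200.0,0.0,2000.0,,,
psth_muscle,Delt Lat,Delt Ant,1840.0,0.0,10000.0,,,
psth_muscle,Pec,Delt Post,0.0,416.0,10000.0,,,
psth_muscle,Bi,PT,0.0,4000.0,10000.0,,,
psth_muscle,Tri,Bi,0.0,2400.0,10000.0,,,
psth_muscle,Brd,Tri,0.0,2320.0,10000.0,,,
psth_muscle,PT,ECR,3680.0,0.0,10000.0,,,
psth_muscle,ECU,ECU,7680.0,0.0,10000.0,,,
psth_muscle,FCR,FCU,4720.0,0.0,10000.0,,,
emga_nerve,Delt Lat,Bi,,,,11.16,0.05,0.9
emga_nerve,Pec,Pec,,,,18.0,0.05,0.9
emga_nerve,Bi,ECR,,,,0.0,0.05,0.9
emga_nerve,Tri,Tri,,,,18.0,0.05,0.9
emga_nerve,Brd,PT,,,,-19.8,0.05,0.9
emga_nerve,ECR,Delt Ant,,,,13.68,0.05,0.9
emga_nerve,FCR,Delt Ant,,,,0.0,0.05,0.9
emga_nerve,FCU,Delt Ant,,,,0.0,0.05,0.9
emga_nerve,FCU,FCU,,,,93.60000000000001,0.05,0.9
emga_tap,Delt Post,Delt Ant,,,,1.035,0.05,0.9
emga_tap,Pec,Bi,,,,0.15750000000000003,0.05,0.9
emga_tap,Bi,FCR,,,,-0.99,0.05,0.9
emga_tap,Tri,ECR,,,,-1.2600000000000002,0.05,0.9
emga_tap,Brd,ECR,,,,1.7550000000000001,0.05,0.9
emga_tap,ECR,PT,,,,2.1149999999999998,0.05,0.9
emga_tap,FCR,Bi,,,,1.4400000000000002,0.05,0.9
emga_tap,FCU,Delt Post,,,,1.845,0.05,0.9
emga_muscle,Delt Post,Delt Post,,,,45.0,0.05,0.9
emga_muscle,Pec,Tri,,,,0.18000000000000002,0.05,0.9
emga_muscle,Bi,FCU,,,,-26.099999999999994,0.05,0.9
emga_muscle,Tri,FCR,,,,-22.5,0.05,0.9
emga_muscle,Brd,FCR,,,,-21.6,0.05,0.9
emga_muscle,ECR,ECR,,,,111.59999999999998,0.05,0.9
emga_muscle,FCR,Tri,,,,-22.5,0.05,0.9
emga_muscle,FCU,Bi,,,,17.099999999999998,0.05,0.9
emga_vib,Delt Post,Pec,,,,-0.48240000000000005,0.05,0.9
emga_vib,Bi,Delt Ant,,,,1.656,0.05,0.9
emga_vib,Tri,Delt Ant,,,,2.9519999999999995,0.05,0.9
emga_vib,Tri,FCU,,,,-2.2319999999999998,0.05,0.9
emga_vib,PT,Bi,,,,3.0959999999999996,0.05,0.9
emga_vib,ECR,ECU,,,,0.0,0.05,0.9
emga_vib,FCR,Brd,,,,-1.0799999999999998,0.05,0.9
emga_vib,FCU,Tri,,,,-1.0799999999999998,0.05,0.9
psth_nerve,Delt Ant,Bi,360.0,0.0,1000.0,,,
psth_nerve,Delt Post,Tri,13.0,0.0,1000.0,,,
psth_nerve,Bi,Pec,24.0,0.0,1000.0,,,
psth_tap,Delt Lat,Delt Ant,230.0,0.0,2000.0,,,
psth_tap,Pec,Delt Post,0.0,52.0,2000.0,,,
psth_tap,Bi,PT,0.0,500.0,2000.0,,,
psth_nerve,Delt Lat,Bi,310.0,0.0,1000.0,,,
psth_nerve,Pec,Pec,500.0,0.0,1000.0,,,
psth_nerve,Bi,ECR,0.0,0.0,1000.0,,,
psth_tap,Delt Post,Delt Ant,230.0,0.0,2000.0,,,
psth_tap,Pec,Bi,35.0,0.0,2000.0,,,
psth_tap,Bi,FCR,0.0,220.0,2000.0,,,
psth_nerve,Delt Post,Delt Post,500.0,0.0,1000.0,,,
psth_nerve,Pec,Tri,2.0,0.0,1000.0,,,
psth_nerve,Bi,FCU,0.0,290.0,1000.0,,,
psth_tap,Delt Post,Pec,0.0,67.0,2000.0,,,
psth_tap,Bi,Delt Ant,230.0,0.0,2000.0,,,
psth_tap,Tri,Delt Ant,410.0,0.0,2000.0,,,
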