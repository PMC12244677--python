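# Per-muscle parameters for the 13 major superficial muscles of the upper limb.
# max_force_N: maximum contractile force for a 50th-percentile male.
# gto_gain_printed_e3: homonymous GTO force-feedback gain as printed (1e-3 MVC/N).
#   Note: the printed ECR/FCR and ECU/FCU gains are mutually swapped relative to
#   k/C with k=1.27; the recomputed column is authoritative (see docs/methods.md).
# afferent_ms / efferent_ms: solved neural conduction delays (milliseconds).
# The last-row abbreviation typo in the source table (FCR for the flexor carpi
# ulnaris) is corrected here.
muscle,name,max_force_N,gto_gain_printed_e3,afferent_ms,efferent_ms
Delt Ant,Anterior Deltoid,1218.9,1.04,4.55,4.37
Delt Post,Posterior Deltoid,1103.5,1.15,4.55,4.37
Delt Lat,Lateral Deltoid,201.6,6.30,4.55,4.37
Pec,Pectoralis Major,658.3,1.93,4.57,8.05
Bi,Biceps,841.9,1.51,6.43,11.94
Tri,Triceps,1489.3,0.85,6.75,11.87
Bra,Brachialis,1177.4,1.08,6.20,11.13
Brd,Brachioradialis,276,4.60,6.09,13.63
PT,Pronator Teres,557.2,2.28,4.65,14.91
ECR,Extensor Carpi Radialis,407.9,2.15,8.89,16.98
ECU,Extensor Carpi Ulnaris,479.8,6.58,9.41,16.93
FCR,Flexor Carpi Radialis,589.8,3.11,9.25,14.95
FCU,Flexor Carpi Ulnaris,192.9,2.65,14.23,18.79
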