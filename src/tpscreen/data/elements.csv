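symbol,nominal,exact_mass,abundance
C,12,12.0,0.9893
C,13,13.00335483507,0.0107
H,1,1.00782503207,0.999885
H,2,2.01410177812,0.000115
N,14,14.0030740048,0.99636
N,15,15.0001088989,0.00364
O,16,15.99491461956,0.99757
O,17,16.99913175650,0.00038
O,18,17.99915961286,0.00205
Na,23,22.9897692809,1.0
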