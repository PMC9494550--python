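# Synthetic fluence-to-H*(10) conversion coefficient table.
# Shape follows the published ICRP 74 ambient dose equivalent curve
# (approximate values, NOT a metrological digitization), extended above
# 201 MeV to 240 MeV by smooth continuation so that spectra with a
# 240 MeV cutoff can be converted.  Edit or replace for real analyses.
energy_MeV,h10_pSv_cm2
1e-09,6.6
1e-08,9
2.53e-08,10.6
1e-07,12.9
2e-07,13.5
5e-07,13.6
1e-06,13.3
1e-05,11.3
0.0001,9.4
0.001,7.9
0.01,10.5
0.02,16.6
0.05,41.1
0.1,88
0.2,170
0.5,322
1,416
2,420
5,405
10,440
20,600
30,515
50,400
75,330
100,285
150,245
201,260
220,270
240,280
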