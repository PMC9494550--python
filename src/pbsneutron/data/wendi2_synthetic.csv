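# Synthetic H*(10) energy response fixture: extended-range moderator monitor with tungsten shell; epithermal over-response, mild high-energy under-response
# NOT measured instrument data; for tests and demonstrations only.
energy_MeV,response
1e-09,0.35
1e-07,0.5
1e-05,1.6
0.001,1.8
0.01,1.4
0.1,1.1
1,1
5,0.95
20,0.9
50,0.85
100,0.8
240,0.8
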