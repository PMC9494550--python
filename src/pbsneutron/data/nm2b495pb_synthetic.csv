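# Synthetic H*(10) energy response fixture: extended-range Andersson-Braun monitor with lead shell
# NOT measured instrument data; for tests and demonstrations only.
energy_MeV,response
1e-09,0.3
1e-07,0.45
1e-05,1.5
0.001,1.6
0.01,1.3
0.1,1.05
1,1
5,0.95
10,0.9
20,0.85
50,0.8
100,0.75
240,0.7
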