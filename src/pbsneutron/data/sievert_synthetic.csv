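# Synthetic H*(10) energy response fixture: variance-method TEPC; epithermal under-response, high-energy over-response
# NOT measured instrument data; for tests and demonstrations only.
energy_MeV,response
1e-09,0.5
1e-07,0.4
1e-05,0.5
0.001,0.6
0.01,0.8
0.1,0.95
1,1
5,1.05
20,1.2
50,1.3
100,1.35
240,1.4
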