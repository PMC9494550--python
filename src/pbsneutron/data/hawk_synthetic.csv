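# Synthetic H*(10) energy response fixture: single-event TEPC; near-unity response on its limited tabulated range
# NOT measured instrument data; for tests and demonstrations only.
energy_MeV,response
0.5,1
1,1
5,1
10,0.98
20,1
60,1.02
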