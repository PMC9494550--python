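# Bundled synthetic monitor response fixtures (see the per-file comments).
monitors:
  wendi2:
    file: wendi2_synthetic.csv
    valid_range: [1.0e-9, 240.0]
  lb6411:
    file: lb6411_synthetic.csv
    valid_range: [1.0e-9, 240.0]
  nm2b458:
    file: nm2b458_synthetic.csv
    valid_range: [1.0e-9, 240.0]
  nm2b495pb:
    file: nm2b495pb_synthetic.csv
    valid_range: [1.0e-9, 240.0]
  sievert:
    file: sievert_synthetic.csv
    valid_range: [1.0e-9, 240.0]
  hawk:
    file: hawk_synthetic.csv
    valid_range: [0.5, 60.0]
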