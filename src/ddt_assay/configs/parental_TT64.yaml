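# Parental (uvrA mutS) strain, single TT(6-4) photoproduct, leading strand.
seed: 20151229
outdir: ddt_results/parental_TT64
experiments:
  parental_TT64_lead:
    strain: parental
    lesion: TT64
    orientation: leading
    construct: pLL1_2c
    n_integrations: 20000
    n_decode: 80
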