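# Recombination-impaired strains, single TT(6-4) photoproduct, plus the
# lesion-free control arm used to estimate the B/D marker-conversion rate.
seed: 20160104
outdir: ddt_results/rec_mutants
experiments:
  recA_TT64_lead:
    strain: recA
    lesion: TT64
    orientation: leading
    n_integrations: 20000
  recF_TT64_lead:
    strain: recF
    lesion: TT64
    orientation: leading
    n_integrations: 20000
  parental_lesion_free:
    strain: parental
    lesion: none
    orientation: leading
    n_integrations: 10000
    n_decode: 80
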