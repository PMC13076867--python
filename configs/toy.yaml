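# Toy end-to-end scenario: small enough to run in seconds, large enough to
# exercise every pipeline stage.
outdir: results/toy
scenario:
  n_genes: 12
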