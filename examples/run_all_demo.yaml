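# Demo configuration for `repeathet run-all --config examples/run_all_demo.yaml`.
# Simulates a small four-library experiment and runs every stage into ./demo_run/.
outdir: demo_run
seed: 17
min_fraction: 0.9       # read-repeat overlap rule (fraction of the shorter interval)
fold_threshold: 100     # ChIP/input enrichment gate, inclusive
flank: 10000            # gene territory extension, bp
which: hfup-reversed    # locus set fed to the gene/GO stages
simulate:
  n_chroms: 2
  chrom_length: 500000
  n_repeats: 150
  n_genes: 25
  library_sizes: {input: 30000, ctrl: 30000, hf: 30000, treat: 30000}
  planted: {hfup_reversed: 4, hfup_static: 4, hfdown_reversed: 4, hfdown_static: 4}
  noise_mode: exact
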