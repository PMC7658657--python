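# slscreen pipeline configuration.
# Every screening threshold is explicit here; omitted fields keep these
# defaults. Output file headers embed a hash of the full config.

seed: 0

thresholds:
  yeast_score_threshold: -0.35   # keep yeast pairs with score <= this
  min_freq: 0.02                 # mutation screen: frequency must exceed this
  min_mut_cancers: 5             # ... in at least this many cancer types
  fc_cut: 1.5                    # DE status: |log2FC| > fc_cut
  alpha: 0.05                    # DE status / log-rank significance level
  min_dysreg_cancers: 11         # dysregulated in more than 10 cancers
  min_up_cancers: 11             # combined screen: partner up in > 10 cancers
  effect_cut: 0.10               # drug association: |mean difference| > 0.10
  fdr_cut: 0.10                  # drug association: BH FDR across drugs
  B: 200                         # randomization draws (headline analyses use 1000)
  min_down_cancers: 4            # miRNA screen: down in >= 4 cancers
  high_freq: 0.03                # high-mutation subset: > 3% in some cancer
  min_characteristics: 4         # core genes carry >= 4 characteristics
  z_cut: 1.96                    # per-patient expression abnormality z cutoff
  min_group: 5                   # smallest usable survival arm

# Synthetic study layout (the generator's planted ground truth).
generator:
  n_genes: 150
  n_cancers: 12
  n_pairs: 30                    # null catalog pairs, on top of planted ones
  n_mut_signal_pairs: 2
  n_expr_signal_pairs: 2
  n_combined_pairs: 3
  n_prognostic_pairs: 2
  n_de_cancers: 11
  n_loci: 24
  n_down_mirnas: 4
  n_drug_effect_pairs: 2

# Cohort sizes.
n_samples_per_cancer: 80         # mutation / survival cohorts
n_tumor: 30
n_normal: 15
dispersion: 0.1                  # NB dispersion of simulated counts
n_isomir_cancers: 4              # cancers profiled for small RNA
survival_scheme: two_group       # or three_group
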