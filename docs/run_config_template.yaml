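# Run configuration template for `ssem-perturb run --config run.yaml`.
# Relative paths are resolved against this file's directory.

seed: 1                                  # master seed (CV fold shuffling)
training_compendium: data/compendium.tsv # genes x samples, tab-delimited
output_dir: results/run1

lasso:
  penalty_mode: cv        # 'cv' (per-row K-fold CV) or 'fixed'
  cv_folds: 5
  # fixed_lambda: 0.05    # required iff penalty_mode: fixed
  max_iter: 50000
  tol: 1.0e-6

# Test experiments: one entry per condition; 'columns' lists the replicate
# columns within the table (omit to use every column). Labels are opaque
# metadata (e.g. exposure time, concentration).
experiments:
  - label: GI10_4ET
    table: data/fl_gi10_4et.tsv
    columns: [rep1, rep2]
  - label: control
    table: data/control.tsv

# Gene sets for ROC/AUC% analysis (newline-delimited ID lists).
gene_sets:
  - data/target_pathway.txt
  - data/orthogonal_pathway.txt

# Single genes tracked in the rank/percentile and RC reports.
target_genes: [YHR007C]
orthogonal_genes: [YDL132W, YAL038W]

# Training-phase modifications: each experiment file is appended to the
# training compendium on its own, the network retrained, and rank changes
# reported for every test experiment.
modifications:
  - label: plus_deletion_strain
    table: data/deletion_experiment.tsv
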