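# Full pipeline configuration. Either a `synthetic:` block (cohort is
# generated) or an `input:` block (paths to on-disk data) must be present.
out_dir: run
seed: 0

min_genes: 400        # cells with fewer detected genes are removed
n_hvg: 500            # highly variable genes kept for PCA
n_pcs: 16
k_neighbors: 20
resolution: 0.2       # SNN modularity resolution
r_min: 0.7            # template-annotation majority threshold
n_bins: 24            # module-score expression bins
n_controls: 100       # control genes per signature gene
tinf_threshold: 10.0  # T-cell % above which a sample is High infiltration
n_perm: 1000          # LR permutation count
alpha: 0.05
min_cells: 50         # subcluster size floor for significant means
p_adjust: bh          # bonferroni | bh

stages:               # any stage can be toggled off
  lr: true
  contrast: true

synthetic:
  demo: true          # use the packaged demonstration cohort

# input:
#   matrix: data/counts.mtx        # + genes.tsv / barcodes.tsv siblings
#   format: mtx                    # or csv
#   cells_are_rows: false
#   cell_table: data/cells.csv     # cell_id,sample_id,site[,histotype,...]
#   template: data/template.csv    # cell_id,cell_type
#   lr_pairs: data/lr.csv          # ligand,receptor,source
#   signatures:
#     cycle_phase: data/cycle.yaml # label -> gene-list file manifest
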