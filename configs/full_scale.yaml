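# Full-scale benchmark: 250 training GRNs of 5 MRs, 100 TFs, 100 genes with
# 3-7 regulators per gene; 50 held-out GRNs (5000 test genes).  Run with e.g.
#   grnsup benchmark --config configs/full_scale.yaml --seed 1 \
#          --m-conditions 50 --out-dir scratch/full_scale
# Takes hours on one CPU.
topology:
  n_mr: 5
  n_tf: 100
  n_g: 100
  d_mr_tf: 3
  d_tf_g_range: [3, 7]
  n_grn: 250
n_grn_test: 50
training:
  max_epochs: 300
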