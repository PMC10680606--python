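# Desk-scale benchmark: trains in minutes on one CPU; same geometry as the
# README worked example.
topology:
  n_mr: 5
  n_tf: 20
  n_g: 20
  d_mr_tf: 3
  d_tf_g_range: [1, 2]
  n_grn: 20
n_grn_test: 10
training:
  max_epochs: 100
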