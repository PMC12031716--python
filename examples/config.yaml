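# Contraction-regime example: shared theta = 0.2, lambda = 0 (reflex elimination)
params:
  theta1: 0.2
  theta2: 0.2
  theta3: 0.2
  theta4: 0.2
  theta5: 0.2
  theta6: 0.2
  theta7: 0.2
  theta8: 0.2
  lambda1: 0.0
  lambda2: 0.0
  lambda3: 0.0
  lambda4: 0.0
  lambda5: 0.0
  lambda6: 0.0
  lambda7: 0.0
  lambda8: 0.0
  u1: 0.5
  u2: 0.5
solver:
  grid_nodes: 1001
  mode: free
  init: identity
  tol: 1.0e-10
  max_iter: 10000
mc:
  x0: 0.5
  depth: 20
  n_paths: 100000
  n_chains: 1000
  n_trials: 100
seed: 0
output_dir: runs/example
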