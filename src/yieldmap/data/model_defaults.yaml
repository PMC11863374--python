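# Frozen hyperparameters for all model families.  Values not listed here fall
# back to the defaults of the pinned scikit-learn version; pinning them in this
# file keeps results reproducible across library upgrades.
linear_least_squares: {}
lasso:
  alpha: 1.0
  max_iter: 10000
bayesian_ridge:
  max_iter: 300
  tol: 0.001
random_forest:
  n_estimators: 100
gradient_boosting:
  n_estimators: 100
  learning_rate: 0.1
mlp:
  hidden_layer_sizes: [100]
  # lbfgs converges reliably on datasets of a few hundred reactions
  solver: lbfgs
  max_iter: 2000
gaussian_process:
  n_restarts_optimizer: 5
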