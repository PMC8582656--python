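# Default hyperparameters per classifier architecture.
#
# These are the documented defaults of the model zoo, not values asserted
# from any study; adjust per project.  Architectures listed under
# `balanced_capable` additionally get an inverse-class-frequency weighted
# variant.
architectures:
  logistic:
    max_iter: 5000
  mlp:
    hidden_layer_sizes: [4]
    max_iter: 3000
  knn:
    n_neighbors: 5
  svc: {}
  decision_tree:
    max_depth: 4
  random_forest:
    n_estimators: 100
    max_depth: 4
  adaboost:
    n_estimators: 50
  gaussian_process: {}
  naive_bayes: {}
  qda: {}
balanced_capable: [logistic, svc, decision_tree, random_forest]
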