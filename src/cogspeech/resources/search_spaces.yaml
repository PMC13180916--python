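# Hyperparameter search spaces, version 1.
# type: int | float | categorical; log: sample in log space.
version: 1
rf:
  n_estimators: {type: int, low: 50, high: 300}
  max_depth: {type: int, low: 2, high: 16}
  min_samples_split: {type: int, low: 2, high: 10}
  max_features: {type: float, low: 0.1, high: 1.0}
xgb:
  n_estimators: {type: int, low: 50, high: 300}
  max_depth: {type: int, low: 2, high: 8}
  learning_rate: {type: float, low: 0.01, high: 0.3, log: true}
  subsample: {type: float, low: 0.5, high: 1.0}
  colsample_bytree: {type: float, low: 0.5, high: 1.0}
  reg_lambda: {type: float, low: 0.001, high: 10.0, log: true}
svm:
  C: {type: float, low: 0.01, high: 1000.0, log: true}
  gamma: {type: float, low: 0.0001, high: 10.0, log: true}
knn:
  n_neighbors: {type: int, low: 1, high: 25}
  weights: {type: categorical, choices: [uniform, distance]}
  p: {type: categorical, choices: [1, 2]}
dt:
  max_depth: {type: int, low: 2, high: 16}
  min_samples_split: {type: int, low: 2, high: 10}
lr:
  C: {type: float, low: 0.001, high: 100.0, log: true}
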