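# Small end-to-end audit: ~2 minutes on one CPU.
# Rows of every report table = context window, columns = algorithm.
seed: 42

corpus:
  n_patients: 300
  name_pool_first: 80
  name_pool_last: 120
  n_diagnoses: 40
  notes_per_patient_range: [2, 4]
  note_len_range: [10, 25]
  background_vocab_size: 800
  association_prob: 0.9

deidentify:
  mode: remove          # remove | tag | replace
  removal_fraction: 0.95

sweep:
  algorithms: [skipgram, cbow, glove]
  windows: [1, 5]
  dim: 50
  min_count: 1
  epochs: null          # per-algorithm defaults

experiments:
  reconstruction_metric: cosine
  association_metric: cityblock
  k: null               # default: half the surviving token count
  thresholds: [2, 5, 10, 25, 50]
  n_perm: 200
  alpha: 0.05
  attack:
    n_trials: 50
    n_targets: 10
    min_count: 10
    k: 5
    direction: farthest
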