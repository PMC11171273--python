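# Desk-scale water pipeline: sample -> dataset -> train, then benchmarks.
molecule: h2o
workdir: runs
scf:
  solver: diis
  grid_level: coarse
sampling:
  mode: perturbation
  n_frames: 400
  temperature: 150
  seed: 0
model:
  max_epochs: 4000
  patience: 300
benchmark:
  ensemble_size: 50
  guesses: [ml, minao, one_electron, atom, huckel, vsap]
  solvers: [sos, diis]
md:
  mode: ml
  n_steps: 500
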