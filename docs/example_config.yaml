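# polbd run example_config.yaml
# Runs the flexible-model d-sweep reproduction with explicit settings.
experiment:
  name: fig7
  n_replicates: 300
  master_seed: 11
  output_dir: results
model:
  v0_kbt: 18.0
  k_pn_nm: 8.56
environment:
  temperature_K: 298.0
  viscosity_mode: constant
integrator:
  dt: 2.0e-5
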