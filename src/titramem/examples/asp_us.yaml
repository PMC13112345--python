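# Aspartate-like acid (aqueous pKa 3.94), umbrella-sampling campaign.
# The US-ext flag adds two higher pH values on the ionized side of the
# simulated ladder (3,4,5,6 -> +7,8).
method: us
replicates: 3
seeds: [101, 102, 103]
ph_ladder: [3, 4, 5, 6]
us_ext: true
diffusion: 0.05
model:
  residue_class: acid
  pka_w: 3.94
  temperature: 300.0
  z_water_ref: 2.0
  shared_terms:
    - {shape: sigmoid-step, amplitude: 50.0, center: -1.2, width: 0.1}
    - {shape: sigmoid-step, amplitude: -50.0, center: 2.3, width: 0.1}
  terms:
    protonated:
      - {shape: gaussian, amplitude: -4.0, center: 0.3, width: 0.3}
    deprotonated:
      - {shape: sigmoid-step, amplitude: 20.0, center: 0.5, width: 0.25}
schedule:
  dt: 0.01
  n_steps: 10000
  titration_period: 20
  record_period: 1
  exchange_period: 20
  exchange_offset: 10
  equilibration_cutoff: 25
windows:
  start: 20
  stop: -12
  spacing: 2
  k_rule:
    - {lo: -12, hi: 20, k: 1000}
analysis:
  n_boot: 200
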