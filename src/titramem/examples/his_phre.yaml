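# Histidine-like base (aqueous pKa 6.54), pH-replica-exchange campaign
# on its standard pH ladder 4.5-7.5.
method: phre
replicates: 2
seeds: [7, 8]
ph_ladder: [4.5, 5.5, 6.5, 7.5]
diffusion: 0.05
model:
  residue_class: base
  pka_w: 6.54
  temperature: 300.0
  z_water_ref: 2.0
  shared_terms:
    - {shape: sigmoid-step, amplitude: 50.0, center: -1.2, width: 0.1}
    - {shape: sigmoid-step, amplitude: -50.0, center: 2.3, width: 0.1}
  terms:
    protonated:
      - {shape: sigmoid-step, amplitude: 20.0, center: 0.5, width: 0.25}
    deprotonated:
      - {shape: gaussian, amplitude: -4.0, center: 0.3, width: 0.3}
schedule:
  dt: 0.01
  n_steps: 10000
  titration_period: 20
  record_period: 1
  exchange_period: 20
  exchange_offset: 10
  equilibration_cutoff: 25
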