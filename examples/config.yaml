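# Example printability configuration: softest characterised gel on the
# default 5-ml syringe train.  Quantities accept explicit unit tags.
label: C20_pH3.7-example

hardware:
  max_torque: "40 N.cm"
  pitch: "0.8 mm"
  efficiency: 0.5
  duty_fraction: 0.8

segments:
  - {kind: cylinder, length: "60 mm", radius: "6 mm"}
  - {kind: cone, length: "10 mm", radius_in: "6 mm", radius_out: "0.2 mm"}
  - {kind: cylinder, length: "16 mm", radius: "0.2 mm"}

material:
  K: 5.78          # Pa s^n
  n: 0.12
  kelvin_voigt:
    E: 30          # Pa
    eta0: 231.4    # Pa s
    nu: 0.49
    G0: 15

support:
  kelvin_voigt:
    E: 1000
    eta0: 1500
    nu: 0.49
    G0: 500

scaffold:
  strand_width: "0.77 mm"
  layer_height: "0.55 mm"
  inter_fiber_distance: "2.57 mm"
  n_layers: 6

process:
  inlet_velocity: "1e-5 m/s"

thresholds:
  shear_stress: 80       # Pa, cell-damage criterion
  collapse_strain: 0.05  # acceptable final strain
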