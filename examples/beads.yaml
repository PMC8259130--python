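# 1:1 mixture of 7 um and 10 um polystyrene beads, valley-gated on the
# size product to select the larger class. Equivalent to
# besselflow.bead_mixture_config(7.0, 10.0, n_each=200).
seed: 1
scene:
  classes:
    - label: bead_7um
      count: 200
      kind: bead
      diameter_mean: 7.0
      diameter_cv: 0.03
      bright_spot: true
      rim_transmission: 0.5
      body_transmission: 0.75
      center_transmission: 1.15
    - label: bead_10um
      count: 200
      kind: bead
      diameter_mean: 10.0
      diameter_cv: 0.03
      bright_spot: true
      rim_transmission: 0.5
      body_transmission: 0.75
      center_transmission: 1.15
gating:
  target_label: bead_10um
  mode: valley
  valley_axis: size_product_um2
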