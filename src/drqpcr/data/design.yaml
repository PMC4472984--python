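# Default experiment design: two contrasting chickpea cultivars, root and leaf,
# water control vs dehydration at 2 h and 5 h, IF4a reference gene.
reference_gene: IF4a
control_treatment_label: water
tolerant_cultivar: ILC482
sensitive_cultivar: Hashem
fold_change_threshold: 2.0
alpha: 0.05
timepoints: [2.0, 5.0]
treatment_labels:
  water: control
  dehydration: stress
  control: control
  stress: stress
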