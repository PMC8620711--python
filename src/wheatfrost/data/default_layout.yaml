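# Default winter-wheat nitrogen trial: 128 varieties (autonamed V001..V128),
# three urea-N gradients, two replicates, three nadir images per plot.
varieties: 128
treatments:
  - {label: N1, rate: 0}
  - {label: N2, rate: 180}
  - {label: N3, rate: 240}
replicates: 2
images_per_plot: 3
plot_size_m: [1.5, 1.5]
rows_per_plot: 6
row_spacing_cm: 25
replicate_kind: biological+technical
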