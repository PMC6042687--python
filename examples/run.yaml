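# Full-pipeline demo: three arm paints + cen/mid/tel band probes on chr2L.
# Run with:  ctquant run --config examples/run.yaml --out scratch/demo
n_cells: 20
seed: 11
simulation:
  nucleus_radii: [2.5, 3.5, 3.5]       # (z, y, x) semi-axes, µm
  voxel_spacing: [0.25, 0.1, 0.1]      # µm
  grid_shape: [64, 128, 128]
  confinement: 0.3                     # compaction dial in [0, 1]
  pairing_prob: 0.9
  channels:
    - {name: chrX}
    - {name: chr2L}
    - {name: chr2R}
  band_probes:
    channel: chr2L
    cen: [0, 15]
    mid: [32, 44]
    tel: [65, 80]
segmentation:
  dna_channel: dna
  min_volume: 0.05                     # µm³ speck filter
report:
  plots: true
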