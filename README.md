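# placegrid

Place-cell formation from bag-of-landmark inputs via sparse autoencoding,
with magnitude-ordered linear prediction that extends a grid-like
representation beyond the explored arena.

The package simulates a unit-square arena surrounded by pseudo-randomly
placed landmark boxes. From every grid point and discrete heading, an
occlusion-aware binary visibility vector over the boxes is recorded and the
per-heading vectors are concatenated into a sparse "bag" input (optionally
masked to a window of headings and sector-normalized). Sparse autoencoders
(spatial top-k or lifetime winner-take-all sparsity, masked reconstruction
loss) compress these inputs; their latent units develop localized,
direction-invariant response fields. Diagnostics cover dead-unit censuses,
winner direction-invariance maps, Delaunay lattice summaries of response
peaks, and a largest-to-second-largest activity ratio that behaves like a
boundary signal. Finally, latent activities are sampled along straight
paths on a fine grid, magnitude-ordered (discarding unit identity), and fed
to linear predictors (Moore-Penrose pseudoinverse or PLS regression) whose
autoregressive rollouts continue the periodic structure beyond the arena.

## CLI

A single entry point with one subcommand per pipeline stage:

```bash
placegrid generate --out runs/data --mask-width 1          # arena + bag dataset
placegrid train    --out runs/model --model "Norm-LT3.33%-LT3.33%-Mask" -v 18
placegrid analyze  --weights runs/model --out runs/analysis
placegrid predict  --weights runs/model --direction 0 --n 60 --steps 200 --out runs/pred
placegrid sweep    --out runs/sweep                        # dead-unit table
placegrid run      --out runs/full                         # whole pipeline
```

All subcommands accept `--config <yaml>` (an `ExperimentSpec`, see
`placegrid.experiment`) and `--seed <int>` to override the master seed.
Model variants use a compact label grammar: `Norm` (per-sector unit-norm
input), `SP<k>` (spatial top-k sparsity), `LT<p>%` (lifetime sparsity),
`DL` (dense layer), `Mask` (loss restricted to visible sectors). One
sparsity token selects the 3-layer net, two tokens the 5-layer net whose
first token governs the 2nd/4th layers and second token the bottleneck.

## Layout

| module | contents |
| --- | --- |
| `placegrid.arena` | arena geometry, box placement, ray-cast visibility, masks, normalization, bag dataset |
| `placegrid.autoencoder` | sparse autoencoder (NumPy, manual backprop, Adagrad/Adam), sparsifiers, masked loss |
| `placegrid.analysis` | response tensors, dead units, winner-invariance maps, Delaunay lattice summary, border statistic |
| `placegrid.prediction` | magnitude ordering, fine-grid sampling, path windows, pseudoinverse/PLS predictors, rollouts |
| `placegrid.experiment` | label grammar, experiment spec, dead-unit sweep, full pipeline |
| `placegrid.benchmark` | reduced-scale reference benchmark used by the acceptance report |
| `placegrid.cli` | click command-line interface |
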