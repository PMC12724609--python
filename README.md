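# spillsmooth

Spatially smoothed per-cell quantification for multiplexed imaging
(Imaging Mass Cytometry and related technologies).

## The problem

IMC measures ~40 protein markers at ~1 μm pixel resolution. Downstream
analysis works on an intensity-per-cell matrix obtained by averaging each
channel over every cell's segmentation mask. Two effects corrupt that
matrix: **batch effects** across acquisitions, and **lateral spillover** —
signal leaking from one cell into its neighbour's quantification because
of limited resolution, 2D projection of 3D tissue, or segmentation error.
`spillsmooth` implements image-level normalization and spillover
correction strategies that act *before or during* aggregation, plus a
fully synthetic dense-tissue simulator with known ground truth to measure
what each strategy buys.

## Methods

* **GZ normalization** — the standardized local Getis-Ord G\* statistic
  applied per pixel:

  `GZ_i = (Σ_{j∈N(i)} w_ij·x_j − X̄·W_i) / ( S·sqrt((n·W_i − W_i²)/(n−1)) )`

  with binary queen-neighbourhood weights (Euclidean distance < 1.5,
  focal pixel included), image mean `X̄` and population sd `S`. GZ acts as
  local smoothing plus per-image standardization; it is exactly invariant
  to per-image affine rescaling `x → c·x + a`, which is what makes it a
  batch correction, and away from image borders it is a monotone affine
  transform of the 3×3 box sum, so it leaves single-marker AUROC
  identical to a 3×3 box blur.
* **SCI1 / SCI2** (spillover-corrected intensity) — per cell, estimate an
  outside-influence field `A` and an inside-contribution field `B` over
  the cell's boundary ring (Gaussian mask-weighted smoothing for SCI1, an
  8-orientation odd Gabor bank for SCI2), subtract `A − B` from the
  boundary pixels, then mean-aggregate.
* **RATI** (random affine transformation intensity) — resample the
  segmentation mask many times by small random per-cell affine transforms
  (scale 0.8–1.2, translation ±1 px, shear ±0.1, rotation ±15°),
  mean-aggregate each resampled mask, and take the per-cell median; the
  iteration spread doubles as a missegmentation diagnostic.
* **Simulator** — densely packed cells (median footprint 31 μm², median
  diameter ~6 μm) as a power-diagram packing with z-correlated slices,
  two-population marker channels (whole-cell or membrane localization),
  smooth background noise, resolution downsampling and Poisson counts.
* **Evaluation** — pair-counting AUROC, max-F1 with threshold, population
  distance, and a kNN inverse-Simpson index for batch mixing.

## Worked example

```python
from spillsmooth.simulate import SimulationConfig, ChannelSpec, simulate_dataset
from spillsmooth.evaluate import method_comparison

ds = simulate_dataset(SimulationConfig(
    field_um=(100.0, 100.0), xy_downsample_factor=4, n_z_slices=4, seed=1,
    channels=[ChannelSpec("ch0", localization="membrane")],
))
truth = ds.truth.set_index("cell_id")["class_ch0"]
print(method_comparison(ds.counts["ch0"], ds.mask, truth,
      methods=("mean", "GZ+mean", "blur+mean", "SCI1", "SCI2", "RATI")))
```

prints (324 simulated cells, 1 μm pixels, 4 z-slices, noisy membrane
marker):

```
   method    auroc  delta_auroc
     mean 0.761150     0.000000
  GZ+mean 0.776545     0.015396
blur+mean 0.777310     0.016160
     SCI1 0.695456    -0.065694
     SCI2 0.654223    -0.106927
     RATI 0.757593    -0.003557
```

`auroc` is the probability that a randomly chosen marker-positive cell
scores above a randomly chosen negative one (0.5 = chance, 1.0 =
perfect); `delta_auroc` compares to plain mean aggregation. Here the
smoothing normalizations (GZ, box blur) recover some separability lost
to resolution and 3D projection, while the boundary corrections do not
help on this densely packed random labelling — the kind of trade-off the
package exists to measure. (GZ+mean and blur+mean differ slightly only
through image-border cells; restricted to interior cells their AUROC is
bitwise identical.)

The same workflows are available from the shell:

```sh
spillsmooth simulate --config sim.yaml --seed 1 --outdir sim/
spillsmooth gz --in sim/ch0.tiff --distance 1.5 --out gz.tiff
spillsmooth rati --img sim/ch0.tiff --mask sim/mask.tiff --iters 25 --seed 1 --out cells.csv
spillsmooth evaluate --cells cells.csv --truth sim/truth.csv --truth-col class_ch0 --out results.csv
```

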