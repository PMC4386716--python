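# camoband

Unsupervised spectral–spatial band selection and camouflaged-region
detection for VNIR (400–1000 nm) hyperspectral cubes.

A camouflaged object — a printed leaf among real leaves, a wig among
hair — mimics its background in most spectral bands but separates in a
few. Supervised detectors need labelled training data that inspection
settings rarely have. This package implements a fully unsupervised
alternative that works on a single test cube:

1. **Spectral ranking.** Each band image is split into two intensity
   classes by exact 1-D two-means and scored with the discriminability

   `D(b) = |μ₁(b) − μ₂(b)| / (σ₁(b) + σ₂(b))`,

   where μᵢ, σᵢ are the class means and standard deviations. Candidate
   bands sit at the local maxima of the smoothed D(b) curve.
2. **Spatial pruning.** Each candidate's binary segmentation is broken
   into connected components (8-connectivity); with `pᵢ = Nᵢ/(S·L)` the
   pixel share of region *i*, the region entropy

   `H(b) = −Σᵢ pᵢ log₂ pᵢ`

   measures spatial fragmentation. The ideal outcome — one object, one
   background — has H ≤ 1 bit, so candidates with H above a ≈1-bit
   threshold are discarded as spatially noisy.
3. **Detection.** Pixels are clustered (two-means, deterministic
   initialisation) over the surviving bands; the minority cluster is
   the camouflaged region.

The package also ships the two classical baselines used for comparison
(PCA loading-curve band selection and full-spectrum profile
clustering), a pixel-level DR/FAR evaluator, ENVI/NPZ cube I/O, and a
synthetic pushbroom-scene generator with planted ground truth so the
whole pipeline is testable without camera data.

## Worked example

```python
import camoband as cb

cube, truth = cb.make_cube(cb.leaf_scene(seed=11, noisy_bands=10))
result = cb.run_pipeline(cube)
for b, h in zip(result.selection.candidates, result.selection.entropies):
    kept = "kept" if b in result.selection.selected else "pruned"
    print(f"band {b:3d}  {cube.wavelengths[b]:7.1f} nm  H = {h:6.3f}  -> {kept}")
m = cb.evaluate(result.detection, truth)
print(f"DR = {m.dr:.1f}%  FAR = {m.far:.4f}%")
```

prints

```
band  16    497.0 nm  H =  1.285  -> pruned
band  32    593.9 nm  H =  1.341  -> pruned
band  50    703.0 nm  H =  0.474  -> kept
band  63    781.8 nm  H =  1.304  -> pruned
band  79    878.8 nm  H =  1.483  -> pruned
band  98    993.9 nm  H =  1.349  -> pruned
DR = 100.0%  FAR = 0.0000%
```

The scene plants a 10% elliptical target whose reflectance differs from
the leaf-like background only near 700 nm, plus ten spatially scrambled
bimodal "noisy" bands. All six candidates are strong two-class bands,
but only the 703 nm one segments into few coherent regions (H = 0.47
bits); the scrambled bands exceed the 1-bit threshold and are pruned.
Detection on the single surviving band recovers every camouflaged pixel
with no false alarms.

The `examples/` scripts walk each capability (scene simulation, band
ranking, pruning + detection, four-method comparison), and the same
stages are available from a shell:

```sh
camoband simulate scene.cfg -o sim/          # scene.cfg: flat key = value
camoband detect sim/cube.npz -o run/         # curve.csv, pruning.csv, mask.png, summary.json
camoband compare sim/cube.npz sim/truth.png  # DR/FAR/bands table for all four methods
```

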