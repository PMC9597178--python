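# plumadrum

Correlated-evolution analysis of plumage colour pattern and drum acoustics:
colour-based image segmentation, colour-pattern geometry statistics, and
phylogenetic generalized least squares (PGLS) with maximum-likelihood
Pagel's λ — plus a synthetic-data module so the whole pipeline is testable
without any external downloads.

## What it does

1. **Segmentation** (`plumadrum.segmentation`) — loads PNG images whose
   non-plumage parts are masked by transparency, downsamples every image to
   a common pixel width (nearest neighbour, never upsampling), histograms
   pixels into 3×3×3 sRGB bins, and agglomeratively merges bin centroids in
   CIE Lab space under a ΔE cutoff (default 45; 55 available via config).
   The result is a colour map: per-pixel class labels, a Lab palette, and
   class proportions.
2. **Pattern metrics** (`plumadrum.pattern_metrics`) — from a colour map:
   chromatic and achromatic boundary strength (transition-frequency-weighted
   mean colour distance across adjacent classes, using the (a, b) plane and
   |ΔL| respectively), scaled Simpson colour diversity, and the red-patch
   proportion (fraction of plumage pixels with L > 55, a > 30, b > 5).
   Also: earth-mover colour distances between images and a neighbour-joining
   colour-similarity tree.
3. **Phylogenetic regression** (`plumadrum.phylo_gls`) — Brownian-motion
   covariance from a Newick tree, Pagel's λ transform, GLS with ML λ
   optimisation, overall F statistics against the intercept-only model,
   body-mass residualisation of drum speed (ordinary regression by default),
   log10 transforms, and a collinearity screen.
4. **Synthetic data** (`plumadrum.synthetic_data`) — plumage-like images
   with analytic ground-truth metrics, pure-birth trees, and trait tables
   evolved with known regression coefficients and λ.
5. **Pipeline + CLI** (`plumadrum.pipeline`, `plumadrum.cli`) — end-to-end
   orchestration producing coefficient tables (term, estimate, s.e.,
   t-value, p-value with λ̂/F/d.f. headers), reversed-direction fits, a
   collinearity matrix, the colour tree and a run log.

## CLI

```sh
plumadrum simulate --n 132 --beta-chromatic 0.15 --lambda 0.9 --seed 1 \
    --images --out-dir sim
plumadrum metrics   --image-dir sim/images --out metrics.csv
plumadrum segment   --image sim/images/T1.png --cutoff 45 --bins 3 --out seg
plumadrum colortree --image-dir sim/images --out colortree.nwk
plumadrum pgls      --traits sim/traits.csv --tree sim/tree.nwk \
    --response speed_resid --lambda ml
plumadrum robustness --image-dir sim/images --widths 160,120,80
plumadrum run       --config config.json
```

`config.json` is a flat JSON document mirroring `pipeline.RunConfig`
(paths, segmentation cutoff, bins per channel, red thresholds, log offset,
λ mode, responses, seed); every run writes its resolved config and a run
log next to the outputs.

## Library quick start

```python
import plumadrum as pdm

img = pdm.load_masked_image("head.png")
cm = pdm.make_color_map(img, cutoff=45)
metrics = pdm.compute_pattern_metrics(img, cm)

tree = pdm.read_newick("tree.nwk")
C = pdm.phylo_covariance(tree, species_list)
fit = pdm.pgls_ml(X, y, C, terms=names)   # lambda by ML
print(fit.summary())
```
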