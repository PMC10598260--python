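# pollenscale

Timescale-dependent variability of Holocene vegetation composition from
fossil pollen records.

Sub-fossil pollen assemblages — the relative abundances of pollen taxa in
dated sediment samples — are the vegetation proxy with the widest
spatio-temporal coverage, but records are short, irregularly sampled and
multivariate. `pollenscale` turns a compilation of such records into
consistent, timescale-resolved estimates of compositional variability and
relates them to vegetation type:

1. **Univariate reduction.** Per record, counts become proportions, are
   square-root transformed (Hellinger), and reduced by PCA of the
   column-centred covariance matrix; the PC1 score series carries the
   locally dominant mode of compositional change.
2. **Haar structure function.** For an irregular series the first-order
   Haar fluctuation at timescale τ is the mean absolute difference between
   the average of the second and first halves of windows of width τ. The
   structure function S(τ) is interpolation-free and robust down to the
   record resolution.
3. **Scaling summaries.** Assuming power-law scaling S(τ) ∝ τ^H, the
   package reports the centennial band mean S_C (τ ∈ [50, 200] yr), the
   millennial band mean S_M (τ ∈ [500, 2000] yr) and the exponent H_CM
   fitted over τ ∈ [200, 3000] yr by a gamma GLM with log link
   (scales weighted by window counts). H relates to the spectral exponent
   by β = 1 + 2H: white noise (β = 0) has H = −0.5, 1/f noise (β = 1) has
   H = 0, the boundary between stationary (H < 0) and drifting (H > 0)
   composition. A 23-ka sinusoidal detrend (linear cos/sin fit)
   optionally removes the orbital-precession-scale trend.
4. **Biome difference axes.** Typical assemblages (mean sqrt assemblages of
   labelled recent samples) are compared pairwise: the difference axis
   a_ij = a_i − a_j cancels shared dominants (Pinus above all) and the
   uncentred projection u_ij(t) of fossil samples onto it classifies a
   record by the sign of its window mean ū_ij. Iterated binary filters
   (forest/open-land → needleleaf/broadleaf → …) refine the classification.
5. **Spatial statistics.** Per-site metrics are gridded (4°×4°), tested
   for spatial coherency with Moran's I (inverse great-circle-distance
   weights, permutation + normal p-values), and correlated with biome
   scores using coverage-weighted Pearson r with permutation significance.

A fully seeded synthetic-data module generates irregular multinomial pollen
records driven by latent signals with known fluctuation exponent H and a
two-biome mixture structure, so every stage is testable end-to-end with
known ground truth and no data download.

## Worked example

```python
import numpy as np
from pollenscale.synthetic import (two_biome_world, gen_surface_set,
                                   FOREST_PROFILE, OPEN_PROFILE)
from pollenscale.pipeline import (PipelineConfig, default_two_biome_chain,
                                  run_pipeline)

records = two_biome_world(n_records=50, H_true=0.0, seed=1)
surface = gen_surface_set(10, {"forest": FOREST_PROFILE,
                               "open_land": OPEN_PROFILE}, seed=2)
cfg = PipelineConfig(axis_chain=default_two_biome_chain(), seed=1)
res = run_pipeline(cfg, records=records, surface_records=surface)

site = res["site_table"]
print("mean H_CM: %+.3f" % site["H_CM"].mean())
u = res["biome_scores"]["Fo,Op"]["u_bar"]
mix = np.array([r.meta["mixture"] for r in records])
print("sign accuracy: %.2f" % np.mean((u.to_numpy() > 0) == (mix > 0.5)))
print(res["correlations"].to_string(index=False))
```

prints

```
mean H_CM: -0.022
sign accuracy: 1.00
axis_id metric         r  p_perm  n
  Fo,Op    S_M -0.302525  0.0367 50
  Fo,Op    S_C -0.757911  0.0518  7
  Fo,Op   H_CM  0.245180  0.0945 50
```

The 50 records carry a latent 1/f driver (true H = 0); the ensemble-mean
fitted exponent, −0.02, recovers it. Every record is classified to the
correct side of the forest/open-land axis from its mean biome score. The
millennial variability S_M correlates negatively with the forest score
even here: for a fixed driver amplitude, the more even open-land
compositions move farther in sqrt-proportion space, so open sites are
intrinsically more variable on this metric (see `docs/methods.md`).

The same pipeline runs from the shell:

```bash
pollenscale synth --n-records 50 --seed 1 --outdir data
pollenscale run --counts data/counts.csv --meta data/meta.csv \
    --surface-counts data/surface_counts.csv \
    --surface-meta data/surface_meta.csv --outdir out --seed 1
```

which writes `site_summary.csv`, per-record and aggregated structure
functions, axis and biome-score tables, gridded metrics, Moran's I and
correlation tables, plus a `manifest.json` with the config hash and seed;
reruns with the same config and seed are byte-identical.

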