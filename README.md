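# sipscape

Statistical image properties of abstract images and their relation to
aesthetic ratings.

Experimental aesthetics has long asked how much of an aesthetic judgment is
carried by the *formal* structure of an image — its complexity,
self-similarity, colour statistics, spectral composition — rather than by
its depicted content. `sipscape` is a tested re-implementation of a full
analysis chain for that question, built around abstract stimuli with no
recognisable content:

1. **Stimulus synthesis** — colored random-phase images with a prescribed
   Fourier spectral slope α (power ∝ f^α over radial frequency; natural
   scenes and artworks cluster near α ≈ −2), plus slope estimation for
   arbitrary images.
2. **Statistical image properties (SIPs)** — scalar descriptors computed at
   a fixed working resolution: HOG complexity, PHOG self-similarity and
   anisotropy, first-/second-order edge-orientation entropies, filter-bank
   variance measures P_a(k)/P_f(k), CIELab/HSV colour statistics, mirror
   symmetry and the Fourier slope.
3. **Predictor selection** — exhaustive/branch-and-bound best-subset
   regression keeping the 10 best models per size by adjusted R², a
   robustness cut, and iterative pruning of collinear predictors
   (Spearman ρ > 0.6), with a PCA model as the reference.
4. **Rating analyses** — standardized-β regressions (|β\*| bands: weak
   < 0.2 ≤ moderate < 0.5 ≤ strong), Kruskal–Wallis + Dunn post-tests,
   quadratic slope-preference curves, inter-rating correlations.
5. **Sweet-spot distances** — squared Mahalanobis distance
   D² = (x − c)ᵀΣ⁻¹(x − c) of each image to the median of a reference
   painting corpus in SIP space, correlated with ratings.
6. **Participant clustering** — k-means on inter-rating correlation
   vectors or slope-preference profiles with elbow/silhouette/gap
   diagnostics and a minimum-cluster-size rule.
7. **Synthetic study generator** — images, a balanced incomplete rating
   design and ratings with planted ground truth (β\* loadings, rater
   archetypes, preference curves), so every stage is verifiable end to end
   without external data.

See `docs/methods.md` for the model conventions and design choices.

## Worked example

```python
import numpy as np
import pandas as pd
from sipscape import (
    RandomPhaseSpec, synthesize_colored_random_phase, measure_fourier_slope,
    standardized_regression, aggregate_ratings,
    SyntheticStudyConfig, generate_ratings, sample_sip_table,
)

# 1. synthesize one stimulus and verify its spectral slope
img = synthesize_colored_random_phase(RandomPhaseSpec(size_px=512, set_slope=-3.0, seed=1))
est = measure_fourier_slope(img)
print(f"set slope -3.0 -> measured {est.slope:.2f} (r^2 = {est.r_squared:.3f})")

# 2. simulate ratings for 150 images and recover the planted coefficients
cfg = SyntheticStudyConfig(seed=1)
rng = np.random.default_rng(1)
sips = sample_sip_table(150, rng)
design = pd.DataFrame(
    [(f"P{p:02d}", i, "style_transferred", float("nan"))
     for p in range(cfg.n_participants) for i in sips.index],
    columns=["participant_id", "image_id", "category", "set_slope"])
ratings, truth = generate_ratings(sips, design, cfg, rng)
agg = aggregate_ratings(ratings)
y = agg[agg.dimension == "Pleasing"].set_index("image_id").loc[sips.index, "rating"]
res = standardized_regression(sips[list(truth.beta_star.columns)], y)
print(f"Pleasing: R2_adj = {res.r2_adj:.2f}")
for name, b, band in zip(res.predictors, res.beta_star, res.effect_bands):
    print(f"  {name:22s} beta* = {b:+.2f} (planted "
          f"{truth.beta_star.loc['Pleasing', name]:+.2f}, {band})")
```

prints

```
set slope -3.0 -> measured -2.96 (r^2 = 0.999)
Pleasing: R2_adj = 0.99
  complexity             beta* = -0.57 (planted -0.57, strong)
  self_similarity        beta* = +0.24 (planted +0.24, moderate)
  entropy_second_order   beta* = +0.08 (planted +0.08, weak)
  variance_Pa_2          beta* = -0.48 (planted -0.49, moderate)
  variance_Pf_30         beta* = +0.57 (planted +0.57, strong)
  lab_b_mean             beta* = -0.40 (planted -0.41, moderate)
  hsv_S_mean             beta* = -0.49 (planted -0.49, moderate)
  entropy_hsv_H          beta* = +0.24 (planted +0.24, moderate)
```

The measured slope sits within the synthesis tolerance of the set value,
and the standardized regression on per-image mean ratings (40 simulated
raters; averaging suppresses the trial noise, hence the high R²_adj)
recovers the planted standardized coefficients and their effect bands.

A command-line interface wraps the same stages
(`sipscape synthesize | sips | select | regress | distance | cluster |
simulate | run`); `sipscape run --seed 7 --out out/` executes the whole
chain on a seeded synthetic study and writes `sips.csv`, `selection.json`,
`results.json`, `dist.json`, `clusters.json` plus a provenance log.

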