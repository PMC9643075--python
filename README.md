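# phylorisk

Trait-based, phylogenetically controlled extinction-risk modelling for
insects (butterflies and odonates), built as a tested, reusable
pipeline.

Conservation assessments ask which intrinsic species traits — body
size, coloration, dispersal ability, range size — predict red-list
status. Because related species resemble each other, raw cross-species
regressions confound trait effects with shared ancestry. `phylorisk`
implements the standard comparative-methods workflow for this problem:

1. **Morphometrics from images.** From dorsal specimen scans (sRGB,
   known dpi) with body/wing masks: body volume
   `V = Σ_r π (n_r s / 2)² s` (each pixel row a cylindrical disc of
   diameter `n_r` pixels and thickness one pixel edge `s = 2.54/dpi`
   cm), color lightness (mean 8-bit gray `(R+G+B)/3` over the body plus
   the third of each wing nearest the body), wing area (pixel count ×
   pixel area), and size-corrected wing area (residuals of
   `ln area ~ ln volume`).
2. **Range occupancy** on an equal-area grid (occupied cells / total
   cells), plus a `vifcor`-style multicollinearity screen (iterative
   pairwise |r| with VIF tie-breaking).
3. **Phylogenetic signal.** Pagel's λ per trait by maximum likelihood:
   `y ~ MVN(μ1, σ² C_λ)` where `C_λ` scales the off-diagonal shared
   branch lengths by λ ∈ [0, 1]; significance by a likelihood-ratio
   test against λ = 0 (χ²₁).
4. **P/S decomposition** under the phylogenetic mixed model
   `y = μ1 + a + e`, `a ~ MVN(0, σ²ₐG)`, `e ~ MVN(0, σ²ₑI)`: ML via
   profiling `h² = σ²ₐ/(σ²ₐ+σ²ₑ)`, then BLUP
   `â = σ̂²ₐ G V̂⁻¹ (y − μ̂1)`; the phylogenetically predicted part is
   `P = μ̂ + â` and the species-specific part `S = y − P` (exactly
   additive).
5. **Ordinal risk models.** Red-list codes on the ordinal scale
   LC=0 < NT=1 < VU=2 < EN=3 < CR=4; proportional-odds regression
   `P(Y ≤ k) = logistic(ζ_k − xβ)` of status on the four traits —
   jointly, so every effect is controlled by range size — fitted three
   times per taxon: on S-components, on P-components, and on raw
   traits.

A first-class synthetic-data module (`phylorisk.synthetic`) generates
every input with known ground truth — Yule trees, λ-Brownian and
mixed-model traits, proportional-odds responses, and rendered specimen
images with analytic volumes/areas — so the whole pipeline is testable
without any external data download.

## Worked example

```sh
phylorisk simulate --n-tips 330 --seed 7 --out demo
phylorisk run --tree demo/tree.newick --traits demo/traits.csv --out demo/results
```

The second command prints the λ table and the three model blocks; for
seed 7 the λ table is

```
          trait   lambda      loglik     loglik0       p_value
    body_volume 0.990303 -181.216603 -460.352911 1.997028e-123
      wing_area 0.921462 -231.955313 -460.915281 1.363174e-101
color_lightness 0.845835 -265.068243 -386.905033  6.219078e-55
range_occupancy 0.377831 -439.006639 -451.473367  5.934357e-07
```

(every trait carries significant phylogenetic signal, strongest for
body volume, weakest for range occupancy) and the S-component block is

```
                 estimate  std_error   z_value   p_value
predictor
body_volume      1.097271   3.369238  0.325673  0.744671
wing_area        0.782621   0.728437  1.074383  0.282651
color_lightness  0.336122   0.472217  0.711796  0.476591
range_occupancy -0.702508   0.172714 -4.067454  0.000048
```

— the simulated study plants a negative risk effect only on the
species-specific part of range size (β = −0.7), and exactly that row
comes out negative and significant (−0.70 ± 0.17, z = −4.07): species
whose range is smaller than their relatives predict are at higher
risk, while in this run every P-block row stays non-significant.
`demo/results/` contains the same tables as CSV plus `report.json`
with seed, config hash and input checksums; a rerun with the same
inputs is byte-identical.

The library mirrors the CLI one-to-one (`simulate_tree`,
`estimate_lambda`, `fit_lynch`, `fit_proportional_odds`,
`run_pipeline`, …) for use from Python.

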