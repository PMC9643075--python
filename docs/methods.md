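# Methods

This note documents the statistical models, the conventions and
defaults behind `phylorisk`, what the synthetic data emulate, and the
package's known limitations.

## Morphometrics

Traits are measured on cropped dorsal specimen images at a known
resolution (default 1200 dpi; pixel edge `s = 2.54/dpi` cm). The
package requires explicit boolean body and wing masks: segmenting real
scans is manual work (the drawings such traits are usually digitized
from were cropped by hand), and building an automatic segmenter would
add an unspecified, error-prone stage. Synthetic images come with
exact masks.

* **Body volume** assumes a cylindrical body with its axis vertical in
  the image: each pixel row is a disc of diameter (body pixels in the
  row × s) and thickness s, so `V = Σ_r π (n_r s / 2)² s` in cm³. The
  row-wise diameter makes the estimate insensitive to taper; the
  dominant error is rounding the body width to whole pixels, about
  `2·Δw/w` relative (≤ 2 % for bodies ≥ 50 px wide, i.e. ≥ ~0.1 cm at
  1200 dpi, but ~10 % for 10-px-wide bodies at 300 dpi — resolution
  matters for narrow bodies).
* **Color lightness** is the unweighted mean of the R, G and B
  channels (0 = black, 255 = white) over the scored region — no
  luminance weighting, since the quantity of interest is reflectance
  for thermoregulation, not perceptual brightness. Butterfly mode
  scores the body plus the third of each wing nearest the body (the
  thermoregulatorily active wing base); odonate mode scores the body
  only. "Nearest third" is operationalized per connected wing
  component as the ⌈fraction × component size⌉ pixels with the
  smallest Euclidean distance to the body mask, ties broken by
  distance then row-major order. A distance rank by pixel count was
  chosen over a geometric chord because it matches the area-based
  definition and is robust to wing shape; it is a declared
  interpretation, not the only possible one.
* **Wing area** is the wing pixel count × s². **Residual wing area**
  (a size-corrected dispersal proxy) is the OLS residual of
  `ln area` on `ln volume` with intercept; residuals sum to zero by
  construction and are invariant to rescaling all volumes.

## Range occupancy and collinearity screening

Range size is occupancy: occupied equal-area grid cells / total cells.
A cell counts as occupied if its intersection with the range polygons
has positive area (a cell-centroid mode exists for sensitivity
checks); map projections and grid construction are out of scope — the
grid is supplied as geometry. Candidate predictors (e.g. flight-period
length, mean annual temperature of occupied cells) are screened with
the `vifcor` convention: repeatedly take the pair with the largest
|Pearson r| and, while it reaches the threshold (default 0.9, exposed
in config since no canonical value exists), drop the member with the
larger variance-inflation factor `VIF_j = 1/(1−R²_j)`; on ties the
higher-index column is dropped so earlier columns survive. Exactly
collinear pairs are handled by the same rule (infinite VIF); constant
columns raise a singularity error naming them.

## Pagel's λ

For a trait y on a rooted tree with covariance `C[i,j]` = shared
root-to-MRCA path length, the λ model is `y ~ MVN(μ1, σ²C_λ)` with
`C_λ` the off-diagonal elements of C scaled by λ. μ and σ² have
closed-form ML solutions given λ (GLS mean, quadratic-form variance),
so the likelihood is profiled on a 101-point grid over [0, 1] followed
by bounded scalar refinement (tolerance 1e-6). The search is bounded
to [0, 1]; the tree-implied theoretical maximum above 1 is not
explored. Significance is a likelihood-ratio test against λ = 0 on
χ²₁; because λ = 0 sits on the boundary this reference is
conservative (empirical size ≈ 0.5× nominal), which is documented
rather than corrected with a 50:50 mixture, matching common practice.
Estimation uses ML, not REML. Traits enter untransformed by default
with a `log_traits` switch for positive size-like traits; both modes
are provided because no single convention is canonical.

## Phylogenetic mixed model (P/S decomposition)

The decomposition model is `y = μ1 + a + e` with `a ~ MVN(0, σ²ₐG)`,
`e ~ MVN(0, σ²ₑI)`, and `G = C/depth` so both variance components are
on the trait scale and the phylogenetic heritability
`h² = σ²ₐ/(σ²ₐ+σ²ₑ)` is interpretable. ML estimation profiles h² over
[0, 1] (same grid-plus-refinement scheme as λ; at fixed h²,
`V ∝ h²G + (1−h²)I` gives closed-form μ̂ and total variance), which
reaches the same optimum as EM iterations on the two variances but is
one-dimensional and well behaved at the h² boundaries. Given the
estimates, `â = σ̂²ₐ G V̂⁻¹ (y − μ̂1)` (BLUP), the phylogenetically
predicted part is `P = μ̂ + â`, and the species-specific part is
`S = y − P`; `P + S = y` holds to machine precision by construction.
On a star phylogeny G = I and h² is unidentifiable; the h² = 0
solution is returned with a flag. Note that the GLS mean centers the
residual in the V-metric (`1ᵀV⁻¹(y−μ̂1) = 0`), so the plain average of
â equals `mean(y) − μ̂` rather than zero.

A gate restricting decomposition to traits with significant λ exists
(`gate_on_signal`), but the pipeline default decomposes every model
trait: the final risk models include all traits in both components,
and in practice all four traits show strong signal anyway.

## Proportional-odds risk models

Red-list codes map to the ordinal threat scale LC=0 < NT=1 < VU=2 <
EN=3 < CR=4; codes outside it (DD, NE, RE) are not orderable and the
species must be excluded, which the pipeline does with a logged
reason. The cumulative-logit model `P(Y ≤ k|x) = logistic(ζ_k − xβ)`
uses the latent-variable sign convention, so positive coefficients
push probability toward more threatened categories. Fitting: BFGS on
an order-preserving threshold re-parameterization (ζ₁ plus
log-increments) from the closed-form intercept-only start
(ζ = logit of cumulative frequencies, β = 0), then Newton polishing in
the natural parameterization until the gradient ∞-norm is below 1e-8.
Standard errors come from the inverse observed information (central
finite differences of the analytic gradient, step 1e-5 — accurate to
far below the SE's own sampling noise); z = β̂/SE and two-sided normal
p-values. Unused response categories are collapsed with a warning;
perfect separation (saturating likelihood) and singular information
raise diagnostic errors naming the offending predictor.

Each component block (S, P, raw) fits one joint four-predictor model —
body volume, wing area, color lightness, range occupancy — so each
effect is controlled by the others, in particular by range size; a
per-trait mode (`joint=False`) fits single-predictor models instead.
If a trait was fitted with h² = 0 its P-component is constant and is
omitted from the P-block with a log note.

## Synthetic data: what it emulates, and what not

Defaults define a study of n = 330 species (the size of the larger,
butterfly data set) on a pure-birth (Yule) tree rescaled to unit depth
(only relative shared branch lengths matter). The four traits follow
the mixed model on a unit-variance scale with per-trait heritabilities
(0.99, 0.93, 0.89, 0.27 for body volume, wing area, color lightness,
range occupancy) taken from the published butterfly λ estimates, since
under the mixed model a trait's λ estimates its phylogenetic variance
fraction. Status is drawn from the proportional-odds model with
thresholds (1.10, 1.73, 2.44, 3.48), chosen so the category mix
mirrors the European red lists (≈75 % LC, 10 % NT, 7 % VU, 5 % EN,
3 % CR), and a single coefficient β = −0.7 on the *true*
species-specific component of range occupancy — the pattern the
analysis should recover. Synthetic specimens have rectangular bodies
(0.08–0.20 cm wide, 0.8–2.0 cm long, the scale of European
butterflies/odonates) and quadrilateral wings at flat gray levels, so
ground-truth volumes and areas are analytic.

Deliberately not emulated: realistic wing shapes or color patterns,
extinct lineages (birth–death trees), non-ultrametric trees,
within-species replicate specimens, non-Gaussian traits. Passing tests
therefore demonstrate estimator correctness under the models'
assumptions, not robustness to their violation on real data.

Reproducibility: every generator takes a seed or numpy Generator;
replicate streams derive from a master seed via
`SeedSequence(master).spawn(n)`. Fixed seed ⇒ bit-identical trees,
traits, responses and images, and byte-identical pipeline output.

## Numerical choices

Grid-then-refine profiling (101 points, xatol 1e-6) for both λ and h²;
Cholesky factorizations throughout with explicit singularity errors; a
flat profile (range < 1e-8) raises the non-identifiability flag rather
than an arbitrary argmax; degenerate traits (zero variance) give
σ̂² = 0 / log-likelihood −∞ and are reported as errors where a fit is
required. Problem sizes in the test and acceptance runs (500-tip trees
for λ recovery, n = 300 for h² recovery, n = 1000 for coverage, 100
replicates for Monte-Carlo medians, 60–100 for end-to-end rates) were
chosen to keep Monte-Carlo error comfortably below the assertion
margins.

## Known limitations

* The estimated P-component of a trait is not orthogonal to its
  species-specific deviation: the BLUP weights each species' own
  observation (G has unit diagonal), so in the weak-signal limit
  `â ∝ G(y − μ̂1)` and `corr(P̂, e) → corr(Ge, e)` ≈ 0.3 on dense
  330-tip trees, *independent of the shrinkage strength*. A purely
  species-specific risk signal therefore bleeds into the P-block with
  a typical |z| around 1.4 at these settings, and the P-block shows a
  spurious significant row in roughly a third of replicates even
  though the S-block detects the true effect essentially always. This
  is a structural property of BLUP-based decomposition — worth
  remembering when interpreting P-component regressions on real data.
* χ²₁ boundary conservatism of the λ test (above).
* Ordinal-model SEs are asymptotic Wald; with few species in the
  threatened categories, profile-likelihood intervals would be more
  reliable.
* No phylogenetic correlation structure inside the ordinal regression
  itself: phylogeny is controlled only through the P/S decomposition,
  by design.
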