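# Methods

This note documents the models, conventions and design choices behind
photoxkit: what each stage computes, which constants and defaults matter,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Optical characterization

**Absorbance.** Spectra are decadic absorbance on a strictly increasing nm
grid with a stated path length (cm). Index positions are evaluated by linear
interpolation; for the 1 nm instrument grid the standard positions (250,
254, 365 nm) fall on grid lines and interpolation is exact.

* E₂/E₃ = A(250)/A(365) — inverse proxy of chromophore molecular size.
* SUVA₂₅₄ = 100·A(254, per cm)/DOC, in L mg-C⁻¹ m⁻¹ — aromaticity proxy.

Denominators ≤ 0 flag the index as undefined (NaN plus a flag field); an
undefined index is never silently reported as zero.

**Fluorescence indices.** EEM intensities are in arbitrary linear units; all
indices are ratios and therefore unit-invariant (a property test asserts
this). Positions snap to the nearest grid line because EEM grids are coarse
(10 nm excitation / 5 nm emission); interpolating would fabricate sub-grid
structure.

* FIX = I(ex 370, em 470)/I(ex 370, em 520)
* BIX = I(ex 310, em 380)/I(ex 310, em 430)
* HIX = Σ I(ex 254, em 435–480) / Σ I(ex 254, em 300–345)

The Ohno-normalized variant HIX = H/(H+L) is available behind a config flag
(`IndexDefinitions.hix_normalized`); the classic ratio is the default. Under
a scatter mask, band sums are taken over unmasked cells and rescaled by
(total cells / unmasked cells), i.e. the full-band sum is estimated from the
surviving cells.

**Rate of light absorption.** Ra = ∫ E(λ)(1 − 10^(−A(λ)ℓ)) dλ is computed
by the trapezoidal rule on the union of the absorbance and flux wavelength
grids restricted to the integration bounds (default 300–600 nm, matching a
lamp with a 300 nm long-pass cutoff). Flux is volumetric
(mol photons L⁻¹ s⁻¹ nm⁻¹); a helper converts spectral irradiance
(W m⁻² nm⁻¹) for a well-mixed layer of given depth. Ra is monotone in
absorbance and in integration width, and the flat-spectrum case converges
under grid refinement — both are tested.

## PARAFAC

The EEM cube (sample × excitation × emission) is decomposed as
X_ijk ≈ Σ_f a_if·b_jf·c_kf with all three factor matrices non-negative.

* **Fitting.** Alternating least squares; each mode update solves a
  non-negative least-squares problem per row, reduced to the factor-rank
  dimension through the Gram matrix and a Cholesky factor (a 1e-12·trace
  ridge guards rank-deficient Grams). Initialization is uniform-random
  non-negative; 10 restarts by default, best final objective wins.
* **Missing data.** Excised (scatter) cells never enter the objective.
  Each sweep imputes them with the current model and then performs exact
  block minimization — a majorize–minimize scheme, so the masked SSE is
  non-increasing per recorded iteration (tested to within accumulated
  round-off, 1e-12 of the total sum of squares).
* **Convergence.** A sweep that improves the masked SSE by less than
  tol·SST (default tol 1e-8), or an SSE below 1e-15·SST, stops the run;
  exhausting max_iter (default 2000) returns the model with
  `converged=False` and a warning.
* **Normalization and order.** Spectral loadings are scaled to unit maximum
  with all scale absorbed into the sample scores; components are ordered by
  descending explained sum of squares before any labelling.
* **Diagnostics.** Core consistency is computed from the least-squares
  Tucker core of the (model-imputed) cube against the superidentity — 100
  for perfectly trilinear structure, sharply negative when over-factored.
  Split-half validation fits two random sample halves independently,
  matches components by summed excitation+emission Tucker congruence
  (Hungarian assignment) and reports the minimum congruence. Component
  labelling against a reference library uses the same matching; mean
  congruence below 0.8 flags the label.
* **Scatter excision** masks |em − ex| ≤ hw₁ (first order) and
  |em − 2·ex| ≤ hw₂ (second order) without altering stored intensities.

Rank is a configuration choice (default 6); the diagnostics inform but do
not automate the choice.

## Probe-kinetics inversion

All experiments are modelled at fixed pH and temperature with triplicate
time courses. Fits are per replicate, then averaged; the standard error of
the replicate mean is carried through every subsequent ratio and difference
in quadrature. Non-positive concentrations are excluded from log fits with
a warning; fewer than 3 usable points is an error.

Channel arithmetic, with the rate-constant table (all values
config-overridable data with citation strings):

| constant | default | meaning |
|---|---|---|
| k(FFA, ¹O₂\*) | 1.0e8 M⁻¹s⁻¹ | FFA + singlet oxygen |
| k_d | 2.2e5 s⁻¹ | ¹O₂\* solvent deactivation |
| Y_phenol | 0.53 | phenol yield per benzene + •OH |
| k(benzene, •OH) | 7.8e9 M⁻¹s⁻¹ | scavenging rate |
| k(TMP, •OH) | 1.9e10 M⁻¹s⁻¹ | TMP correction term |
| k(TMP, ¹O₂\*) | 6.0e7 M⁻¹s⁻¹ | TMP correction term |
| k(TMP, ³C\*) | 3.0e9 M⁻¹s⁻¹ | TMP + oxidizing triplets |
| k_q′ | 2.8e5 s⁻¹ | pseudo-first-order ³C\* quenching |
| f_iso | 0.22 | c,c-HDO yield per ³C\* + HDO encounter |

* **¹O₂\*** (FFA decay, •OH quenched by isopropanol):
  [¹O₂\*]ₛₛ = k_obs/k(FFA,¹O₂\*); production = [¹O₂\*]ₛₛ·k_d.
* **•OH** (phenol formation from excess benzene): production = R₀/Y_phenol;
  [•OH]ₛₛ = production/(k(benzene,•OH)·[benzene]). R₀ is the slope of the
  early linear segment (points with product below 10% of the precursor's
  initial concentration, minimum 3). Benzene outside 0.1–100 mM warns
  (outside the scavenging design).
* **³C\*_TMP**: k_corr = k_obs,TMP − k(TMP,•OH)[•OH]ₛₛ −
  k(TMP,¹O₂\*)[¹O₂\*]ₛₛ; [³C\*]ₛₛ = k_corr/k(TMP,³C\*). A negative
  corrected rate — expected under noise when the triplet signal is small —
  is floored at zero and flagged rather than raised.
* **³C\*_HDO**: the c,c-HDO formation rate is fitted at ≥3 initial HDO
  concentrations (default 0.025–0.5 mM); 1/R versus 1/[HDO]₀ is linear for
  saturation kinetics, so the intercept gives the saturation rate R_max
  exactly, and production = R_max/f_iso. A non-positive intercept flags
  extrapolation failure. The default truths keep Φ(TMP) > Φ(HDO), the
  order typically observed, but because one k_q′ serves both triplet
  channels, [³C\*_HDO]ₛₛ tracks Φ(HDO) here; a channel-specific conversion
  constant could be configured if the two pools should be scaled
  independently.

Every Φ is production/Ra by definition; values outside [0, 1] are flagged,
never clipped silently.

## Association layer

Responses are ln(Φ) and ln([RI]ₛₛ) per channel; rows with undefined features
or non-positive responses are excluded per model with a logged count.

* **Correlation.** Spearman ρ with average ranks for ties and t-distribution
  p-values; stars at p < 0.05/0.01/0.001; Benjamini–Hochberg-adjusted
  p-values are reported alongside the raw ones (the star display follows
  common practice of annotating raw p-values; the adjusted column is the
  defensible alternative). Pairs need ≥ 5 complete observations; constant
  columns are flagged undefined.
* **MLR.** Predictors are standardized; forward selection adds, per step,
  the feature with the largest 5-fold cross-validated MSE reduction and
  stops below a relative improvement of 1e-6 — so an exactly collinear
  duplicate is never added. The final model is refit by OLS on the raw
  scale (statsmodels); selected designs with condition number above 1e6 are
  pruned with a warning. Reported: coefficients with standard errors, R²,
  RMSE, CV R², CV RMSE.
* **Gradient-boosted trees.** Least-squares boosting (scikit-learn) with
  hyperparameters chosen by 5-fold grid search over
  {trees: 100/300, learning rate: 0.05/0.1, depth: 2/3, subsample: 1/0.8}.
  With ≥ 20 samples the data is split 80/20 (optionally stratified by
  series) and test metrics reported; below that the model runs CV-only and
  test metrics are NaN, flagged. A constant response short-circuits to a
  trivial model with undefined R² and zero importances.
* **Interpretation.** Impurity importances are normalized split gains;
  permutation importance is the mean training-MSE increase over 20 shuffles.
  Shapley attributions use Monte-Carlo permutation sampling (≥ 32
  permutations) with one training-row background per permutation; the base
  value is the training-set mean prediction, and the efficiency identity
  holds exactly against the sampled-background mean (the training-mean base
  differs only by that mean's Monte-Carlo error, whose per-sample standard
  error is returned). Partial dependence averages predictions over a
  quantile-spaced grid (grid size 1 evaluates at the median).

These are deliberate, logged substitutes for tool-brand choices common in
this literature: cross-validated forward selection in place of OPLS
predictor filtering, grid search in place of Bayesian hyperparameter
optimization, and a single boosted ensemble in place of a five-algorithm
comparison. The scientific outputs tested here — which features drive the
yields, and the predictive R² — do not depend on those brands.

## Synthetic-data generator

The generator reproduces the study design so the whole chain is testable by
parameter recovery:

* **Samples.** Per series (COM, EPS): one bulk sample plus up to six MW
  fractions at a fixed DOC of 5 mg C/L. Protein rises and polysaccharide
  falls with MW; EPS carries more polysaccharide and less protein than COM.
* **Components.** Six Gaussian-peaked fluorophores at literature-typical
  positions — flavin-like (ex 370/450, em 520), tyrosine-like (275/305),
  tryptophan-like (280/340), HULIS-1 (250/450), fulvic-like (320/420),
  HULIS-2 (280/500) — peak-normalized on the instrument grids; every pair
  has joint ex⊗em Tucker congruence below 0.95. With MW, protein-like
  scores rise and flavin-like plus humic-like scores fall, which makes BIX
  rise and FIX and HIX fall across fractions, as observed for such samples.
* **Spectra.** Absorbance is exponential in wavelength, parameterized so
  that SUVA₂₅₄ rises (1.5→3.5 L mg-C⁻¹ m⁻¹ for COM) and E₂/E₃ falls (7→4)
  across fractions. The lamp is a smooth 300 nm-cutoff spectrum with peak
  volumetric flux 3e-6 mol photons L⁻¹ s⁻¹ nm⁻¹ — an intense xenon-lamp
  setting chosen so probe decays are well measurable within the sampling
  windows — giving Ra of order 1e-5 mol photons L⁻¹ s⁻¹.
* **Truths.** Quantum yields decrease log-linearly across fractions (slope
  0.40 per step; C1 values 10% for ¹O₂\*, 4.5% for ³C\*_TMP, 3% for
  ³C\*_HDO, 0.4% for •OH; EPS at 0.85× COM; bulk = fraction mean). These
  magnitudes sit in the upper range reported for efficient atmospheric
  photosensitizers. [RI]ₛₛ truths follow from production = Φ·Ra and the
  constants table, so both Φ and [RI]ₛₛ decrease with MW and the
  steady-state ordering •OH ≪ ³C\*_TMP < ¹O₂\* holds.
* **Kinetics.** Probe time courses are exact first-order decays / linear
  product formations implied by the truths, in triplicate, with optional
  multiplicative Gaussian noise (clipped at zero). Sampling windows are 5 h
  for FFA and benzene/phenol, 30 min for TMP, 20 min for HDO.
* **Determinism.** Truths depend only on the configuration; the seed drives
  noise only. The same seed reproduces every value bit-identically
  (including through the CSV round trip, which writes shortest
  round-trip float representations); different seeds share identical
  truths.

**What the generator does not emulate** — hence what passing tests do and do
not show about real data: inner-filter distortion of EEMs, detector drift
and wavelength-dependent instrument response; probe direct photolysis and
light screening; deviations from first-order kinetics (probe depletion,
sensitizer photobleaching — real absorbance and fluorescence decline under
irradiation); pH/temperature effects; and structured (non-Gaussian,
correlated) measurement error. Recovery results certify the inversion
arithmetic and fitting code under the stated model, not robustness to these
effects.

## Numerical choices and degenerate inputs

* Kinetic slope fits use ordinary least squares with a free intercept; a
  constant series gives rate 0 and R² defined as 1 (zero residuals).
* Replicate pooling: mean of per-replicate estimates; SE of that mean (the
  regression slope SE when only one replicate exists).
* PARAFAC ties and degeneracies: zero factor columns make core consistency
  undefined (NaN); all-zero sample scores flag that sample's fractions
  undefined; assignment ties break deterministically by component order.
* Pipeline stage seeds derive from one global seed via a CRC-keyed
  `SeedSequence`, so stages have independent streams controlled by a single
  knob, and two runs with the same seed write byte-identical tables.
* Scale sizes in the shipped checks: the default study is 14 samples
  (2 series × 7); PARAFAC recovery uses a 20-sample cube; Monte-Carlo
  recovery properties use 100 generator seeds at 2% noise — sizes chosen to
  make the statistical assertions stable while keeping the suite quick.

## Known limitations

* The EEM intensity scale is arbitrary; only ratio-based indices and
  scale-invariant fractions are interpreted. No Raman-unit calibration.
* HIX/BIX/FIX positions use nearest-grid-line lookup; on very coarse or
  shifted grids the effective positions can differ from nominal by up to
  half a grid step.
* The rate-constant table is a set of literature-typical defaults; absolute
  [RI]ₛₛ and Φ values scale directly with these constants and should be
  recomputed with a lab's preferred values (one YAML override).
* The 14-sample default study is below the 20-sample threshold for a
  train/test split, so the tree-ensemble layer runs CV-only there; split
  metrics require larger designs.
* Monte-Carlo Shapley values carry sampling error of order
  sd(prediction)/√(permutations) per feature; exact tree-path algorithms
  are out of scope.
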