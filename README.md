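# photoxkit

Photosensitized oxidant production by chromophoric organic matter in the
aqueous phase: a reusable analysis chain from optical spectra and
chemical-probe kinetics to apparent quantum yields, plus the statistical
layer linking oxidant production to measurable sample properties.

## Who this is for

Environmental photochemists characterizing dissolved or aerosol-derived
organic matter — for example cellular organic matter (COM) and extracellular
polymeric substances (EPS) from bacteria, bulk and molecular-weight (MW)
ultrafiltration fractions — who measure:

* UV–visible absorbance spectra and excitation–emission matrix (EEM)
  fluorescence;
* irradiation time courses of the standard chemical probes — furfuryl
  alcohol (FFA) for singlet oxygen (¹O₂\*), benzene→phenol for hydroxyl
  radical (•OH), 2,4,6-trimethylphenol (TMP) for oxidizing organic triplet
  excited states (³C\*), and *t,t*-2,4-hexadien-1-ol (HDO) for the larger
  energy-transfer ³C\* pool;

and want the derived quantities such studies report: optical indices (E₂/E₃,
SUVA₂₅₄, BIX, FIX, HIX), PARAFAC fluorophore components, steady-state
oxidant concentrations [RI]ₛₛ, apparent quantum yields Φ_RI, and the
correlation / regression / tree-ensemble analysis of what drives them.

## The chain

1. **Spectra** (`photoxkit.spectra`). Absorbance, EEM and lamp photon-flux
   containers with CSV I/O; indices; and the wavelength-integrated rate of
   light absorption

   Ra = ∫ E(λ) (1 − 10^(−A(λ)ℓ)) dλ  [mol photons L⁻¹ s⁻¹],

   the denominator of every quantum yield.

2. **PARAFAC** (`photoxkit.parafac`). Non-negative trilinear decomposition
   of the EEM cube, X_ijk ≈ Σ_f a_if b_jf c_kf, fitted by masked
   alternating least squares with restarts: `Parafac(cube, 6).fit()` returns
   a results object with scores, loadings, explained variance, core
   consistency (CORCONDIA), split-half validation, per-sample component
   fractions, and congruence-based matching against a component library.

3. **Kinetics inversion** (`photoxkit.photokin`). First-order decay and
   initial-rate fits per replicate with pooled uncertainties, then the probe
   arithmetic: [¹O₂\*]ₛₛ = k_obs/k_FFA; •OH production = R₀(phenol)/Y_phenol;
   TMP decay corrected for its •OH and ¹O₂\* losses; HDO saturation
   extrapolated by a double-reciprocal fit. Each channel yields
   Φ = production / Ra.

4. **Association** (`photoxkit.assoc`). Spearman correlation matrix with
   significance stars, forward-selected multiple linear regression,
   a cross-validation-tuned gradient-boosted tree ensemble, impurity and
   permutation importances, Monte-Carlo Shapley attributions, and partial
   dependence.

5. **Synthetic data** (`photoxkit.synthio`). A generator that emulates the
   study design — six fluorophore components, monotone MW trends in indices
   and yields, first-order probe kinetics in triplicate — with a full ground
   truth, so every stage is testable by parameter recovery.

`photoxkit.pipeline.run_pipeline` orchestrates all stages from one YAML
config, and a thin CLI wraps it:

```
photoxkit generate --out ds/ --seed 3
photoxkit run --dataset ds/ --out run/ --seed 3
photoxkit indices|parafac|oxidants|assoc --dataset ds/
```

## Worked example

```python
from photoxkit import SynthConfig, gen_dataset, recover_oxidants
from photoxkit.spectra import compute_indices

ds = gen_dataset(SynthConfig(), seed=1)      # 2 series x (bulk + 6 MW fractions)
rec = recover_oxidants(ds)                   # probe kinetics -> oxidants
for sid in ("C0", "C1", "C6"):
    r = rec[sid]["singlet_oxygen"]
    idx = compute_indices(ds.absorbance[sid], ds.eems[sid], 5.0)
    print(f"{sid}:  phi(1O2*) = {100*r.phi:5.2f} %   [1O2*]_ss = {r.riss_M:.2e} M   "
          f"E2/E3 = {idx.e2_e3:.2f}   SUVA254 = {idx.suva254:.2f}")
```

prints

```
C0:  phi(1O2*) =  4.60 %   [1O2*]_ss = 3.69e-12 M   E2/E3 = 5.50   SUVA254 = 2.50
C1:  phi(1O2*) = 10.00 %   [1O2*]_ss = 3.72e-12 M   E2/E3 = 7.00   SUVA254 = 1.50
C6:  phi(1O2*) =  1.35 %   [1O2*]_ss = 2.19e-12 M   E2/E3 = 4.00   SUVA254 = 3.50
```

C0 is the bulk COM sample and C1…C6 its MW fractions from <1 kDa to >50 kDa.
The singlet-oxygen quantum yield is highest for the smallest fraction (10%)
and falls with MW, while E₂/E₃ (inverse chromophore size) falls and SUVA₂₅₄
(aromaticity) rises — the trend structure the analysis layer then quantifies
(Spearman ρ of Φ vs E₂/E₃ ≈ +0.95, vs SUVA₂₅₄ ≈ −0.91 on this dataset).
Because the dataset is synthetic, every recovered number can be checked
against `ds.truth`; on noiseless data the recovery is exact to ≈1e-15
relative.

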