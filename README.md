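# tissuemrs

Classification of breast tumor versus non-involved adjacent tissue from
HR MAS ¹H-MR spectra of intact biopsies.

During breast-conserving surgery the surgeon needs to know, within
minutes, whether the resection margin still contains tumor. High
resolution magic angle spinning (HR MAS) MRS acquires liquid-like
metabolite spectra from intact tissue, and the tissue metabolome —
elevated choline-containing metabolites (especially phosphocholine),
glycine, taurine and lactate, with depleted glucose — separates tumor
from non-involved tissue. `tissuemrs` implements the complete analysis
chain for this problem, from raw spectral matrix to validated
classification report, for anyone building or auditing such classifiers
on CPMG-style 1D tissue spectra.

## What it implements

**Preprocessing** (`tissuemrs.preprocess`), in order: selection of the
−0.08–4.7 ppm region; replacement of negative spikes by boundary
values; offset removal; asymmetric-least-squares baseline subtraction
(minimize Σᵢ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)², wᵢ = p where yᵢ > zᵢ else 1−p;
defaults λ = 10⁷, p = 10⁻⁴, d = 2); interval correlation-shift peak
alignment (39 intervals, reference = highest mean correlation);
deletion of the region upfield from 3.0 ppm, the ethanol window
(3.642–3.691 ppm) and the fatty-acid residual window (4.200–4.400 ppm);
mean normalization. On the default grid this leaves 2759 variables.

**Chemometrics** (`tissuemrs.chemometrics`), from first principles:
PCA; modified VAST scaling x′ᵢⱼ = (xᵢⱼ − mⱼ)·(mⱼ/sⱼ) with mⱼ, sⱼ
estimated on training data only; PLS-DA (NIPALS PLS1: wₐ ∝ Xᵀy,
tₐ = Xwₐ, pₐ = Xᵀtₐ/tₐᵀtₐ, qₐ = yᵀtₐ/tₐᵀtₐ, deflate; b = W(PᵀW)⁻¹q);
and VIP scores VIPⱼ = √(P·Σₐ SSYₐ wⱼₐ² / Σₐ SSYₐ) with
SSYₐ = qₐ² tₐᵀtₐ, normalized so mean(VIP²) = 1.

**Validation** (`tissuemrs.validation`): patient-grouped Monte-Carlo
double cross-validation — two nested leave-20%-out loops, the inner
(20 repetitions) selecting the latent-variable count and the outer
(80 repetitions) estimating accuracy, sensitivity and specificity —
with whole patients always confined to one side of every split, VAST
refitted inside every loop, and permutation testing with the add-one
p-value.

**Labeling schemes** (`tissuemrs.schemes`): four ways of handling
low-tumor-content biopsies (tumor ≥5% vs <5%; tumor >0% vs 0%; and the
>0% rule with 0<TC<5% or 0<TC≤5% samples excluded from training and
scored as tumor), plus a classifier restricted to the
choline-metabolite window (3.252–3.196 ppm).

**Synthetic cohorts** (`tissuemrs.synthetic`): because clinical biobank
spectra are not public, a generator produces cohorts with the assumed
statistical structure — 328 samples from 228 patients in four
tumor-content strata, metabolite levels tied to tumor content with a
shared patient random effect, baseline drift, shift jitter, ethanol
contamination, and noise — so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from tissuemrs import DCVConfig, generate_cohort, preprocess_pipeline
from tissuemrs.schemes import run_scheme

spectra, meta = generate_cohort()          # default cohort, seed 0
print(f"cohort: {spectra.n_samples} spectra x {spectra.n_variables} points, "
      f"{meta['patient_id'].nunique()} patients")
pp = preprocess_pipeline(spectra)          # full preprocessing chain
print(f"preprocessed: {pp.n_variables} variables "
      f"({pp.ppm.max():.3f} to {pp.ppm.min():.3f} ppm)")
cfg = DCVConfig(n_outer=20, n_inner=10, seed=0)
rep = run_scheme(pp, meta, "tumor_gt0", cfg, rng=0)
print(f"scheme {rep.scheme}: accuracy {rep.accuracy_pct}%, "
      f"sensitivity {rep.sensitivity_pct}%, specificity {rep.specificity_pct}%, "
      f"median LVs {np.median(rep.chosen_A):.0f}")
```

Output:

```
cohort: 328 spectra x 9088 points, 228 patients
preprocessed: 2759 variables (4.700 to 3.000 ppm)
scheme tumor_gt0: accuracy 88%, sensitivity 97%, specificity 53%, median LVs 4
```

The report says: over 20 outer cross-validation repetitions, held-out
patients' samples were classified correctly 88% of the time; 97% of
tumor-containing biopsies were recognized, while only about half of the
(much rarer) 0%-tumor biopsies were — the class imbalance (263 vs 65)
pushes the fixed 0.5 decision threshold toward the tumor class. The
inner loops typically selected 4 latent variables.

The same pipeline is available from the shell:

```sh
tissuemrs simulate --out-spectra spectra.tsv --out-meta meta.tsv
tissuemrs preprocess --in-spectra spectra.tsv --out pp.tsv
tissuemrs evaluate --in-spectra pp.tsv --in-meta meta.tsv --scheme tumor_gt0
tissuemrs report --in-spectra pp.tsv --in-meta meta.tsv --out table.tsv
```

## Layout

- `src/tissuemrs/io.py` — spectra/metadata containers, delimited-text and
  JCAMP-DX readers, run configuration
- `src/tissuemrs/synthetic.py` — cohort generator
- `src/tissuemrs/preprocess.py` — preprocessing chain
- `src/tissuemrs/chemometrics.py` — PCA, VAST, PLS-DA, VIP
- `src/tissuemrs/validation.py` — grouped double CV, metrics, permutation
- `src/tissuemrs/schemes.py` — labeling schemes, choline subset, reports
- `src/tissuemrs/cli.py` — command-line interface
- `docs/methods.md` — model assumptions, parameter choices, limitations
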