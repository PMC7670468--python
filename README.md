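# marginrad

MR-radiomics analysis of the peri-conization margin for identifying
residual cervical disease.

After conization for carcinoma in situ of the cervix, some patients
harbor residual disease that standard MR reading cannot reliably detect.
This package implements, as a tested and reusable pipeline, a radiomics
analysis of the band of uterine tissue surrounding the conization cavity:

1. **VOI construction** — the ≤5 mm shell of uterine tissue outward of
   the cavity, built from uterus and cavity segmentation masks and
   cleaned by an in-plane disk erosion.
2. **Image preparation** — ADC maps from a two-b-value DWI pair via
   ADC = ln(S₀/S(b))/b, z-score normalization over the uterus, and
   fixed-bin-count gray-level discretization.
3. **Feature extraction** — a fixed catalogue of 94 features per
   sequence (first-order, shape, GLCM, GLDM, GLRLM, GLSZM, NGTDM) on the
   T2-weighted volume and on the ADC map over the identical VOI.
4. **Repeatability filtering** — intra-/inter-observer ICC against
   repeated delineations; features with ICC ≤ 0.75 are discarded.
5. **All-relevant selection and modeling** — Boruta (shadow features,
   binomial hit tests with Benjamini–Hochberg FDR) against a plain
   random-forest baseline on all surviving features, plus the clinical
   positive-margin flag; AUCs compared with the paired DeLong test.
6. **Survival validation** — the trained model stratifies a
   uterine-preservation cohort into high/low risk; disease-free survival
   is compared by Kaplan–Meier and the log-rank test.

Patient MRI of this kind is not public, so the package ships a
first-class synthetic phantom generator (`marginrad.synthetic`) that
produces cohorts with the geometric and statistical structure the
analysis assumes — ellipsoid uterus with a conization cavity, DWI pairs
consistent with a prescribed ADC field, focal diffusion-restricting
lesions in the margin band of residual cases, noisy positive-margin
flags, rater-perturbed segmentations for ICC, and censored follow-up —
so every stage is testable end to end. See `docs/methods.md` for the
model, conventions and generator details.

## Worked example

```python
from marginrad.pipeline import StudyConfig, run_stage1, run_stage2

cfg = StudyConfig(seed=0)          # 110-case phantom cohort, 1:1 split
report = run_stage1(cfg)           # VOI -> features -> ICC -> Boruta -> models
stage2 = run_stage2(cfg, report)   # risk groups -> KM / log-rank
```

The same run is scripted as a narrative under `analysis/`:

```
$ python analysis/01_simulate_cohort.py --seed 0
generated 110 phantom cases (29 residual, PM sens/spec 0.724/0.568);
noiseless ADC reconstruction error 4.34e-19 mm^2/s

$ python analysis/02_build_model.py --seed 0
94 features per sequence; ICC>0.75 kept 113 (19 T2WI + 94 ADC);
Boruta confirmed 7 all-relevant features
test AUC: RF 0.902, Boruta 0.913, PM 0.561
DeLong Boruta vs RF: p = 0.712; Boruta vs positive margin: p = 0.0000

$ python analysis/03_validate_survival.py --seed 0
risk groups: 4 high / 24 low; 5 events in 36 months (high: 4, low: 1)
log-rank: chi2 = 25.97, p = 0.0000
```

Reading the numbers: of the 188 extracted features, 113 survive the
ICC > 0.75 repeatability filter and Boruta confirms 7 as all-relevant.
On the held-out half the Boruta-subset model discriminates residual from
nonresidual phantoms (AUC 0.913) better than the positive-margin flag
(AUC 0.561, DeLong p < 10⁻⁴) and about as well as the all-features
forest at this seed (the Boruta > RF ordering is a majority-of-seeds
property, not a per-seed guarantee). In the preservation cohort, 4 of
the 5 follow-up events fall in the model's high-risk group and the
disease-free-survival curves separate (log-rank p < 10⁻⁴).

A thin CLI mirrors the stages: `marginrad synth`, `marginrad voi`,
`marginrad run-all` (see `marginrad --help`).

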