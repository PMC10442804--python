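# dosestrat

Risk stratification of radiotherapy patients from multi-organ dose-volume
histograms (DVHs), for late patient-reported toxicity in head-and-neck
(oropharyngeal) cancer.

Radiation plans that deliver similar mean doses can distribute dose very
differently across organs at risk (salivary glands, pharyngeal
constrictors, larynx, ...), and it is the joint multi-organ pattern that
drives lasting symptoms such as xerostomia (drymouth), swallowing
difficulty, excess mucus and voice dysfunction. `dosestrat` implements an
unsupervised pipeline that:

1. encodes every patient as a vector of dose-at-volume features
   (V25...V60 in 5% steps per organ, e.g. 5 organs x 8 features = 40
   doses for drymouth), after relabeling paired left/right organs as
   ipsilateral/contralateral by the patient's higher-dose primary side;
2. fits a 3-component **Bayesian Gaussian mixture** to those vectors and
   names the component with the highest total mean organ dose the
   **high-dose (HD) cluster**;
3. distills HD membership into a minimal conjunction of dose-threshold
   rules ("contralateral submandibular V45 > 61 Gy AND contralateral
   parotid V45 > 0") via a **mutual-information beam search** — the
   **simplified high-dose (SHD) group**;
4. tests both stratifications against clinical confounders with
   likelihood-ratio tests (p, odds ratio, ΔAIC/ΔBIC) and chi-square /
   Fisher-exact association tables, including published organ dose-limit
   flags;
5. benchmarks All / HD / SHD risk scores against recalibrated logistic
   **NTCP** (normal-tissue complication probability) models in stratified
   5-fold cross-validation, reporting AUC-ROC and Matthews correlation.

Binary endpoints per symptom are MDASI-style 0–10 ratings at 6 months:
`rating > 4` (late severe) and `rating − baseline > 4` (severe change);
missing baselines are filled by a denoising autoencoder trained on the
full longitudinal questionnaire.

A first-class synthetic-cohort generator (`dosestrat.synthetic_data`)
plants three latent dose groups with correlated organ DVHs, paired-organ
asymmetry, covariate enrichment and a configurable logistic outcome model,
so the whole pipeline is testable without patient data.

## Worked example

```bash
dosestrat simulate --n 300 --seed 1 --outdir demo/
dosestrat cluster  --dvh demo/dvh.csv --spec drymouth --k 3 --seed 1 \
                   --features-out demo/features.csv --out demo/model.json
dosestrat mine-rules --features demo/features.csv --model demo/model.json \
                   --out demo/rules.yaml
dosestrat evaluate --dvh demo/dvh.csv --clinical demo/clinical.csv \
                   --symptoms demo/symptoms.csv --symptom drymouth \
                   --seed 1 --lrt-out demo/lrt.csv --out demo/cv.csv
```

Output on this synthetic cohort:

```
wrote 300-patient cohort to demo
fit 3-component model; HD cluster = 2
rules: contralateral_submandibular:V30 > 56  precision=1.000 recall=1.000
          All      NTCP        HD       SHD
AUC  0.864599  0.860382  0.772301  0.776612
MCC  0.586491  0.514325  0.586491  0.593730
```

Reading: the mixture recovered the planted high-dose group exactly (the
single mined threshold — dose to 30% of the contralateral submandibular
gland above 56 Gy — reproduces HD membership with precision = recall =
1), and in 5-fold cross-validation all dose-informed stratifications
predict the late severe-drymouth endpoint far above chance, the 3-level
stratification on par with the recalibrated NTCP logistic model. (On
strongly separated synthetic outcomes the per-fold NTCP fits can hit the
documented ridge fallback for separation; a warning is logged.) On synthetic cohorts the dose→outcome
effect is configurable, so absolute AUCs depend on the planted effect
size. The same commands run unchanged on real exports: a long-format DVH
CSV (`patient, roi, dose_gy, volume_fraction`), a clinical covariate CSV
and a long-format symptom CSV (`patient, timepoint, symptom, rating`).

Equivalent library calls: `generate_cohort`, `build_feature_matrix`,
`fit_bgmm` + `identify_hd`, `beam_search_rules`, `cluster_lrt_suite`,
`cross_validate`.

## Layout

- `src/dosestrat/dvh_io.py` — DVH CSV I/O, validation, lateralization
- `src/dosestrat/dose_features.py` — Vx / mean / max features, feature matrix
- `src/dosestrat/clustering.py` — Bayesian GMM, HD identification
- `src/dosestrat/rule_mining.py` — MI beam search, SHD rules
- `src/dosestrat/outcomes.py` — symptom tables, eligibility, imputation, endpoints
- `src/dosestrat/stats_tests.py` — LRT/AIC/BIC, chi², Fisher, dose limits
- `src/dosestrat/evaluation.py` — risk scores, NTCP, cross-validation
- `src/dosestrat/synthetic_data.py` — planted-structure cohort generator
- `docs/methods.md` — modeling assumptions and design choices
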