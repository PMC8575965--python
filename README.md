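# minerva-nsclc

Predictive-biomarker analysis for two-arm survival cohorts: screen genomic
alterations for **treatment-by-gene interactions** in Cox proportional-hazards
models, combine the selected markers into a composite **interaction-z-weighted
score** (the MINERVA score), stratify patients into three
treatment-preference subgroups, and validate the signature by repeated
cross-validation with in-fold marker reselection.

The motivating setting is resected *EGFR*-mutant stage II–IIIA non-small-cell
lung cancer randomized between adjuvant EGFR-TKI (gefitinib) and
vinorelbine + cisplatin chemotherapy, where five predictive markers were
identified: *RB1* alterations, copy-number gains of *NKX2-1*, *CDK4* and
*MYC*, and *TP53* exon 4/5 missense mutations. The patient-level trial data
are restricted-access, so the package ships a synthetic cohort generator that
emulates the cohort's statistical structure (arm sizes, marker prevalences,
published interaction hazard ratios) and every pipeline stage is fully
exercisable without any download.

## The model

For a binary gene feature `g` with treatment assignment `r` (1 = TKI,
0 = chemo), the predictive screen fits the Cox model

```
h_i(t) = h0(t) · exp( ψ1·r_i + ψ2·g_i + ψ3·r_i·g_i )
```

and tests the interaction ψ3 with the Wald statistic `z = ψ3 / se(ψ3)`; the
interaction hazard ratio is `iHR = exp(ψ3)` and negative z means the
alteration shifts relative benefit toward the TKI arm. Features with
interaction p < 0.05 form the signature; each patient's composite score is

```
score_i = Σ_{g ∈ G} z_g · p_{i,g}
```

with `p_{i,g}` the 0/1 alteration status. The published weights are
`RB1_alt: 2.88, NKX2-1_gain: −2.72, CDK4_gain: −2.26, TP53_e45_mis: −2.11,
MYC_gain: −1.98`. Patients are stratified at score cutoffs (−0.5, 0.5) into
Highly TKI-Preferable (score ≤ −0.5), TKI-Preferable and Chemo-Preferable
(score ≥ 0.5) subgroups, and within-subgroup relative benefit is summarised
by the 2-year survival-rate ratio and the median survival difference between
arms.

## Worked example

```python
import minerva_nsclc as mn

cfg = mn.default_adjuvant_config(seed=0)          # 171 patients, 95 TKI / 76 chemo
clinical, calls, truth = mn.generate_cohort(cfg)
fm = mn.build_feature_matrix(clinical, mn.filter_variants(calls),
                             mn.feature_definitions_for(cfg))

results, selected = mn.screen_interactions(fm, clinical)
print(mn.results_to_frame(results).to_string(index=False))
```

```
     feature events/altered      iHR (95% CI)     z       p  status
     RB1_alt          26/31 7.46 (2.88-19.33)  4.14     0.0      OK
    MYC_gain           6/15  0.04 (0.00-0.39) -2.81  0.0049      OK
 NKX2-1_gain          21/32  0.27 (0.10-0.72) -2.62  0.0087      OK
TP53_e45_mis          17/27  0.31 (0.10-0.96) -2.04  0.0413      OK
   CDK4_gain            3/7                                 SKIPPED
```

The screen recovers the planted effects: this cohort realization drew only 7
CDK4-gain patients, below the default `min_altered=10`, so that feature is
reported SKIPPED rather than unreliably fitted. Scoring and stratifying with
the published weights:

```python
scorer = mn.MinervaScorer(weights="published").fit(None)   # sklearn-style
scored = scorer.score_result(fm)
print(scored.subgroups.value_counts().to_dict())
# {'TP': 90, 'HTP': 58, 'CP': 23}

interaction = mn.score_interaction_test(scored, clinical)
print(interaction.z, interaction.p)   # 6.87, 6.4e-12
```

The composite score itself interacts strongly with treatment. Per-subgroup
benefit (`mn.benefit_summary(scored, clinical)`) on this cohort shows the
expected directions — HTP: 2-year DFS rate 84.8% (TKI) vs 12.0% (chemo),
7.1-fold ratio, treatment HR 0.06; CP: 21.4% vs 77.8%, ratio 0.28, HR 3.5 —
i.e. HTP patients benefit dramatically from TKI while CP (RB1-altered)
patients fare better on chemotherapy.

Cross-validation with in-fold reselection (`mn.ten_fold_cv`) and LOOCV
(`mn.loocv`) reproduce the stratification out-of-fold; see
`docs/methods.md` for the validation contracts.

A CLI wraps the same pipeline:

```sh
minerva-nsclc simulate --n 171 --seed 0 --out cohort/
minerva-nsclc screen   --clinical cohort/clinical.tsv --alterations cohort/alterations.tsv --out screen/
minerva-nsclc score    --clinical cohort/clinical.tsv --alterations cohort/alterations.tsv --out score/
minerva-nsclc validate --clinical cohort/clinical.tsv --alterations cohort/alterations.tsv --out cv/
```

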