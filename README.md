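# rectalresponse

Pre-treatment genomic comparison of **complete responders (CR)** and
**incomplete responders (ICR)** to neoadjuvant chemoradiotherapy (nCRT) in
locally advanced rectal cancer, packaged as a tested, reusable pipeline.

Only 20–40% of stage 2/3 rectal cancers respond completely to nCRT, and no
genomic predictor of response is in clinical use. Working from MAF-style
somatic mutation calls and a clinical table, this package implements the
analysis stages used to contrast CR and ICR tumors before treatment:

1. **Variant filtering and tumor mutation burden** (`cohort_io`) — exclude
   calls with depth < 30 or allele fraction < 0.1, keep nonsynonymous coding
   classes, binarize into a samples × genes mutation matrix, and compute
   TMB = mutations / coding megabase.
2. **Matching-weight propensity balancing** (`balance`) — fit the propensity
   of complete response e(x) by logistic regression on clinical covariates
   (age, gender, BMI, tumor size, stage), weight samples by
   w = min(e, 1−e)/e (CR) or min(e, 1−e)/(1−e) (ICR), and revise the model
   (squares, then interactions) until every weighted standardized difference
   is < 10%; compare TMB between the balanced groups with a weighted Welch
   t-test.
3. **Mutation networks** (`mutnet`) — Fisher-exact CR/ICR contrasts for genes
   above 5% frequency, co-occurrence / mutual-exclusivity calls for the top
   mutated gene pairs (OR > 1 and p < 0.05 → co-occurring; OR < 1 → mutually
   exclusive), DNA-repair panel fractions with a Yates chi-squared test, and
   CR-/ICR-specific classification of external significance q-values.
4. **Complete-response prediction** (`response_model`) — bivariate Fisher
   screening (p < 0.1) of gene and co-occurring-pair indicators, construction
   of the model features (tumor size, AJCC stage, any-screened-gene
   indicator, and the 0 / 1–2 / 3-or-more co-occurring-mutation category),
   logistic fits of both count functional forms, selection by lowest AIC with
   a Tjur R² tie-break, and training-set sensitivity / specificity / PPV /
   NPV.
5. **Synthetic cohorts** (`synthetic_cohort`) — a generator that emits
   clinical tables and MAF files with known, recoverable structure:
   confounded CR assignment, group-shifted gene frequencies, planted
   co-occurring pairs (latent-factor construction calibrated to a target
   odds ratio), sub-threshold decoy variants, and an optional closed-loop
   mode where the response labels are regenerated from known logistic
   coefficients.

The statistical primitives behind all of this (exact 2×2 tests, BH
adjustment, weighted t-test, standardized differences, IRLS logistic MLE
with Tjur R²) live in `statcore`.

## Worked example

Simulate the reference 364-patient cohort (104 CR / 260 ICR, confounded
assignment, two planted co-occurring repair-gene pairs) and run the three
analysis stages:

```sh
rectalresponse simulate --preset paperlike --seed 7 --out demo
rectalresponse balance --clinical demo/clinical.tsv --maf demo/mutations.maf \
    --covariates age,gender,bmi,tumor_size --out demo/out
rectalresponse network --maf demo/mutations.maf --clinical demo/clinical.tsv --out demo/out
rectalresponse predict --maf demo/mutations.maf --clinical demo/clinical.tsv --out demo/out
```

which prints:

```
balance converged=True after 1 iteration(s); max weighted SMD 3.43%
weighted TMB t-test: estimate=0.128 p=0.0000
4 co-occurring and 2 mutually exclusive pair(s) of 105 tested
selected categorical count form: AIC=373.01 Tjur R2=0.154 n=364
training metrics (optimistic, same-cohort screening): sensitivity=0.125 specificity=0.969 ppv=0.619 npv=0.735
```

Reading the output: the propensity weighting reduced the worst covariate
imbalance from 52% (tumor size, see `demo/out/balance_report.tsv`) to 3.4%,
after which the planted CR excess in mutation rate (+0.128 mutations/Mb on
the 1.5 Mb panel footprint) is detected by the weighted t-test. The network
stage tests all pairs of the top 25 genes above 5% frequency and recovers
the planted co-occurring pairs. The prediction stage selects the categorical
count form and reports training-set (optimistic) classification metrics;
`demo/out/model_summary.tsv` holds the per-term odds ratios with 95% Wald
intervals, e.g. tumor size OR 0.76 (0.64–0.90) — larger tumors predict
incomplete response.

The published cohort-level numbers from the real MSK/TIMING/UM data require
the cBioPortal `rectal_msk_2022` download and are kept as gated replication
targets in `rectalresponse.replication`.

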