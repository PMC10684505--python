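# glp1alc

Tools for two linked analyses of how GLP-1 and GLP-1/GIP agonist
medications (semaglutide, tirzepatide) relate to alcohol consumption:

1. **Theme attribution of social-media discussions.** A corpus of posts
   about these medications is cleaned, embedded, clustered with k-means
   (k chosen at the knee of the distortion curve), merged into named
   themes, and characterised by one-vs-rest random-forest feature
   importances and n-gram tables.  Alcohol-related posts are located by
   keyword, tested for per-theme enrichment with an exact upper-tail
   hypergeometric probability, classified as reduction-related against a
   phrase lexicon ("stopped", "reduced", "don't want", ...), summarised
   as prefix/suffix word trees, and related over time through
   full-order partial correlations of monthly theme shares.

2. **Remote-survey alcohol outcomes.** Survey instruments (30-day TLFB
   drinking diary with sex-specific binge thresholds, AUDIT, BAES,
   drinks per episode) are scored and modelled with random-intercept
   mixed models — Poisson for daily drink counts, binomial for daily
   binge indicators, Gaussian for instrument scores — with fixed effects
   chosen among {Group, Time, Group×Time} by BIC.  An a priori
   repeated-measures ANOVA power computation (noncentral F) reproduces
   the study's sample-size arithmetic.

Real social-media corpora and participant records are not
redistributable, so the package ships synthetic-data generators with
known ground truth: a corpus generator that plants topics, keyword rates
and reduction phrases, and a cohort generator that draws drinking
diaries and instrument responses from the published model coefficients.
Every pipeline stage is validated against that ground truth.

## The models in brief

For participant *i* on day *j*, daily drinks follow

  log E[y_ij] = β₀ + β_w·weekend_ij + β_g·group_i + β_gw·group_i·weekend_ij + u_i,  u_i ~ N(0, σ²_u)

with the binge indicator following the analogous logistic model.  The
marginal likelihood integrates u_i out by Gauss–Hermite quadrature;
coefficients are reported as incidence-rate ratios / odds ratios with
Wald 95% CIs, and BIC = −2·loglik + p·log(n).  For themes, the
full-order partial correlation between two theme series is the
correlation of their residuals after regressing both on all remaining
theme series; on simplex-constrained shares one theme is dropped from
each control set (see `docs/methods.md`).

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on
synthetic data, writing tables under `results/`:

```
$ python analysis/01_simulate_corpus.py
wrote 8000 posts from 1500 users -> results/corpus
alcohol posts planted: 468 (70.9% reduction-related)
$ python analysis/03_cluster_themes.py
knee detection selected k = 6 over k in 2..12
$ python analysis/05_keyword_alcohol.py
468 keyword posts (468 occurrences)
most enriched theme: 1 (k=303 of n=468 keyword posts, p=9.87e-57)
reduction-related: 332/468 (70.9%) of alcohol posts
```

The knee detector recovers the six planted topics; alcohol posts are
strongly enriched in the theme where they were planted; and the
reduction classifier recovers the planted 70% rate.  On the survey side:

```
$ python analysis/08_survey_models.py
drinks: best fixed structure ('group', 'time', 'group:time') (BIC 11037.7)
  group[semaglutide]: B=-1.231 (SE 0.114, IRR 0.29)
  time: B=0.872 (SE 0.035, IRR 2.39)
binge: best fixed structure ('group', 'time') (BIC 2514.5)
  time: B=1.299 (SE 0.108, OR 3.67)
$ python analysis/09_power_analysis.py
medication participants required: 76 (achieved power 0.954)
total with an equal-proportion control group: 114
```

BIC selection recovers the generating fixed structures (the drinks model
was generated with a group×weekend interaction, the binge model
without), the estimates sit near the generating coefficients (weekend
0.85, semaglutide −1.31 on the log-rate scale; weekend 1.4178 on the
log-odds scale), and the power computation reproduces the 76/114
sample-size arithmetic.

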