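# Methods

This note records the models the package implements, the defaults it
chooses where the procedure leaves a decision open, what the synthetic
generators do and do not emulate, and the numerical choices that matter.

## Text pipeline

**Cleaning.** Title and body are merged (title tokens first), URLs are
removed before tokenisation, text is lowercased and split into runs of
`[a-z0-9]` with internal apostrophes preserved, and stopwords are
dropped.  The stopword list is pinned in `glp1alc.stopwords` rather than
taken from an NLP library, for reproducibility; it deliberately *keeps
negation forms* (`no`, `not`, `don't`, `never`), because the reduction
lexicon matches phrases such as "don't want" whose meaning lives in the
negation.  Deduplication (exact match on cleaned text, earliest
timestamp kept) runs before the length filter; the length filter drops
posts whose cleaned text joined by single spaces is under 100
characters.  Applying the filter to cleaned rather than raw text is a
choice: cleaning precedes filtering in the pipeline's narrative order,
and the filter's purpose (content depth) refers to surviving content.

**Embedding.** The default encoder is a deterministic feature-hashing
bag-of-tokens encoder: 512 dimensions, signed hashing, L2
normalisation.  It requires no model download, is exactly reproducible,
and separates planted topics well; it does not capture synonymy or word
order, so absolute distortion values are not comparable to those of a
pretrained sentence encoder.  Any encoder implementing
`encode_tokens(docs) -> (n, d) array` deterministically can be plugged
in.

**Cluster count.** k-means (Euclidean, k-means++, best of `n_init=10`,
fixed seed) is swept over k; the distortion (within-cluster sum of
squared distances) curve is min–max normalised on both axes and the
knee is the point of maximum perpendicular distance from the chord
joining the endpoints, ties toward the smallest k.  A curve that is
linear after normalisation (max distance ≤ 1e−9) yields "no knee"
rather than an arbitrary k.

**Merging.** Cluster merging into themes is supported two ways: an
explicit merge map (mirroring manual thematic inspection), and an
automated proposal that merges clusters whose top-n unigram sets have
Jaccard similarity ≥ 0.5, closed transitively.  Merging never splits a
raw cluster, so co-clustered posts stay together.

**Theme characterisation.** Per-theme one-vs-rest random forests (200
trees, fixed seed) are trained on unigram+bigram count features with
document frequency ≥ 5; token features were chosen over embedding
features because the reported "features" of a theme are words.
Impurity importances are reported, so the weights of any reported
subset sum to at most 1.

**Enrichment.** For each theme the upper-tail hypergeometric
probability P(X ≥ k) of its keyword-post count is computed by exact
log-space summation (gammaln terms, log-sum-exp), which is stable at
corpus-sized N where naive factorial ratios overflow.  Raw p-values are
reported alongside Bonferroni-adjusted values for the g simultaneous
theme tests.

**Word trees.** For each keyword occurrence, up to `max_depth` cleaned
tokens before (prefix; stored nearest-first) or after (suffix) are
aggregated into a count-weighted trie rooted at the keyword; nodes
below `min_count` are pruned.  A node is highlighted when the phrase
along its path (read in natural order, keyword included) contains a
reduction-lexicon phrase.

**Theme dynamics.** Posts are binned by calendar month (the period
length is otherwise undefined; monthly bins keep ≥ T = g+3 periods on
multi-year corpora), counts are row-normalised to shares, and empty
months are flagged and excluded.  The full-order partial correlation of
themes i and j regresses both on the remaining theme series (with
intercept) and correlates the residuals; p-values use
t = ρ·√(df/(1−ρ²)), df = T − 2 − n_controls, two-sided.

*Compositional caveat.*  Shares are simplex-constrained: for any pair,
x_i + x_j = 1 − Σ(controls), so regressing on **all** remaining themes
forces the two residual vectors into exact anti-collinearity and every
partial correlation degenerates to −1.  The implementation therefore
drops one theme from each pair's control set — the smallest theme by
total count that is not itself a member of the pair — giving g−3
controls per pair and a well-defined statistic.  A counts mode
(`values="counts"`) avoids the constraint entirely and uses all g−2
controls; both are exposed because the original procedure does not say
which scale it correlated.

## Survey pipeline

**Scoring.**  AUDIT: items 1–8 score their option index (0–4), items
9–10 are three-option items scored 0/2/4; total 0–40.  BAES: items 1–7
stimulative, 8–14 sedative, each 0–10, subscale totals 0–70.  TLFB: a
binge day is ≥ 5 drinks for males, ≥ 4 for females.  Weekend defaults
to Friday/Saturday/Sunday (configurable; the instrument itself defines
no weekend).  Scoring is exact integer arithmetic with explicit errors
for missing or out-of-range items — no imputation anywhere.

**Cohort comparisons.**  Continuous characteristics are compared by
one-way equal-variance ANOVA reconstructed from group means/SDs/sizes
(SSB about the weighted grand mean, SSW = Σ(nᵢ−1)sᵢ²); categorical ones
by Pearson chi-square without continuity correction.  With three
groups a t-test is not defined for the comparison; the ANOVA
reconstruction reproduces the published p-values of the cohort table
(e.g. age 0.0503 vs printed 0.051), with residual disagreement bounded
by the 2-decimal rounding of the printed summaries (~±0.003 on p).

**Mixed models.**  All outcome models carry a participant random
intercept.  Poisson (log link) and binomial (logit link) families
maximise the exact marginal likelihood, integrating the random
intercept by non-adaptive Gauss–Hermite quadrature with 201 nodes;
observations are collapsed to (participant, design-row) sufficient
statistics first, so the cost is independent of diary length.  201
nodes matches lme4's adaptive 25-node quadrature to ~1e−5 on
cohort-sized problems (the package's test suite cross-checks this via
Rscript); 25 non-adaptive nodes were insufficient (~0.02 coefficient
error) because the integrand concentrates as per-participant
information grows.  Gradients are analytic (posterior-weighted scores);
standard errors come from the finite-difference observed information.
The variance MLE may sit on the σ_u = 0 boundary, where the model
collapses to the plain GLM; the fitter checks the boundary explicitly
and returns the GLM solution when the interior optimum does not beat
it.  The Gaussian family is delegated to statsmodels `MixedLM` with
full maximum likelihood (not REML) so that BIC values are comparable
across fixed-effect structures.

**Model selection.**  Candidates are {Group}, {Time}, {Group+Time},
{Group+Time+Group×Time}; the interaction is never fit without its main
effects.  BIC = −2·loglik + p·log(n_obs), with p counting fixed effects
plus variance parameters (random intercept; plus residual variance for
Gaussian).  Ties prefer the simpler model; non-converged fits are
excluded with a warning.

**Power.**  The a priori sample size uses the conventional
repeated-measures, within-factor ANOVA parameterisation: noncentrality
λ = f²·N·m·ε/(1−ρ), numerator df (m−1)ε, denominator df (N−k)(m−1)ε,
power from the noncentral F.  Defaults ρ = 0.5 and ε = 1 are the
conventional calculator defaults.  With f = 0.25, α = 0.01, target
power 0.95, k = 2 groups and m = 2 measurements the smallest adequate N
is 75, rounded up to 76 for equal allocation; adding an
equal-proportion control group gives 76 + 76/2 = 114.  A Monte-Carlo
simulation of the corresponding split-plot F test confirms the
achieved power within 0.01.

## Synthetic generators

**Corpus.**  Each topic owns a keyword lexicon (disjoint lexicons in
the test configurations) and a weight on the simplex; posts draw ~70%
of tokens from their topic lexicon and ~30% from a shared filler
vocabulary, so clusters are separable but not trivially so — this
stresses the knee detector rather than handing it orthogonal point
masses.  Alcohol-flagged posts (per-topic rates) embed the literal
token "alcohol" inside a planted phrase; with probability
`reduction_rate` the phrase carries a reduction-lexicon match, so
`classify_reduction` has known ground truth.  Timestamps are uniform
over the date range, with an optional late-surge (beta-weighted) mode
mimicking the posting-volume explosion of recent years.  The generator
makes no attempt to mimic real language: passing tests demonstrate
that the pipeline recovers planted structure, not that it would find
the same themes in real Reddit text.

**Cohort.**  Defaults are the published study conditions: group sizes
47/56/50 (control/semaglutide/tirzepatide), drinks model coefficients
(weekend 0.85; group −1.31/−1.54; group×weekend −0.17/−0.45 on the log
scale), binge model coefficients (weekend 1.4178; group
−2.0517/−3.7920 on the logit scale; no interaction).  Values the study
does not report are fixed once: drinks intercept log(1.5) (≈1.5 drinks
on a control weekday), binge intercept −1.5 (weekday control binge
probability ≈0.18), random-intercept SD 0.5 on the linear-predictor
scale (a moderate heterogeneity consistent with overdispersed drinking
data), male fraction 29/153.  Instrument scores are generated by
drawing a participant-level target total (pre-period mean/SD per group,
plus a post-period shift equal to the published within-group effects:
AUDIT −6.63, episodes −2.34, BAES stimulative −9.06 / sedative −9.69)
and distributing it over items uniformly at random under each item's
range cap, with items 9–10 of the AUDIT allocated in 2-point steps;
item totals therefore score back exactly.  Only subscale totals are
modelled — item-level response patterns are not meant to be realistic.
The drinks and binge outcomes are drawn from separate linear predictors
with independent random intercepts; the generator does not couple a
day's binge indicator to that day's drawn drink count.

## Known limitations

- The hashed encoder cannot reproduce semantic clusterings of a
  pretrained sentence encoder; corpus-level results (theme counts,
  shares, enrichment counts) on real data are out of reach by design.
- Non-adaptive quadrature needs many nodes when participants carry many
  observations; the 201-node default is sized for diaries of tens of
  observations, not thousands.
- Partial correlations on shares depend on the control-drop rule;
  conclusions that flip between the proportions and counts modes should
  be treated as fragile.
- Random slopes, GEEs and profile-likelihood CIs are out of scope; CIs
  are Wald with z = 1.96.
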