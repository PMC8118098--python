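# Methods

`nonwordvar` implements a pipeline for quantifying how consistently the same
people read the same nonwords aloud across repeated sessions, and for testing
what drives that variability: an item-level predictor derived from
grapheme-phoneme statistics, a participant-level literacy composite, and the
session dynamics of pronunciation change.

## Item consistency from grapheme-phoneme entropies

A grapheme-phoneme correspondence (GPC) table is tallied from a syllabified
phonemic lexicon.  Syllables are segmented into graphemes by greedy
leftmost-longest match over a declarative inventory (bundled default: the
single letters as fallback, common English multigraphs, and context rules
such as C and G softened before E/I/Y).  A parsed grapheme token is
attributed to its most specific satisfied rule — context-conditioned beats
position-conditioned (word-initial/final, syllable-initial/final) beats
unconditioned, ties broken by inventory order — so "context-dependent
grapheme" means a (spelling, position, following-letter-set) unit.  Only
syllables whose grapheme count equals their phoneme count are tallied
(discards counted), giving an unambiguous positional pairing.  Per rule,
relative frequencies are the per-phoneme counts divided by the rule total,
and the pronunciation uncertainty is the Shannon entropy
H = sum_i(-p_i ln p_i) in nats: 0 for a deterministic grapheme, ln k for a
uniform k-way one.  Counting is type-weighted by default (each unique
word/pronunciation pair once); token weighting via a frequency column is
available, since corpus practice varies and the choice is not theoretically
forced.

A nonword is scored by syllabifying it (a manual overrides table is
authoritative; the fallback locates vowel groups — vocalic Y after a
consonant, silent lone final E, syllabic final consonant+LE — and splits
intervocalic clusters by onset maximisation over a legal-onset list),
parsing each syllable with the same inventory, averaging grapheme entropies
within syllables, taking the maximum across syllables and negating:

    raw = -max_syll( mean_graphemes(H) )

so 0 means fully predictable and strongly negative means many plausible
pronunciations.  Alternative aggregations (mean/sum over syllables, worst
single grapheme) are exported, and `select_metric` reproduces the
pick-the-best-correlate step against any dependent variable.  Graphemes
missing from the table fall back to their letters' unconditioned rules; a
letter absent from the table is an error, never a silent zero.

**Covariate transform.** The raw metric is nonpositive, so a direct log
transform is undefined.  The model covariate is `-ln(H_maxsyll + eps)`
centred over the analysed item set, with `eps = 0.01`; this keeps the
higher-is-more-consistent orientation while compressing the right tail.
Both `eps` and the variant (`neg_log` or plain centred `raw`) are
configuration keys, because the exact transform is a genuinely open choice.

## Response statistics

The central input is a long table (participant, session, item, phonemic
transcription).  Transcriptions are normalised — NFC, whitespace trimmed,
stress marks stripped (stress is deliberately ignored) — and pronunciation
identity is exact string equality thereafter; no phonetic similarity metric
is applied, matching the definitions of the statistics below.  Sessions per
participant must form a contiguous block 1..s_max (dropout of later
sessions allowed, gaps not).

* **Distinct counts / response diversity.** Per participant x item, the
  number of different pronunciations across sessions, and the entropy (nats)
  of the empirical pronunciation distribution over sessions: 0 when
  identical everywhere, ln 5 ≈ 1.6 when all five sessions differ.
* **Novelty coding.** For sessions ≥ 2, a response is novel (1) iff that
  participant never used it for that item in an earlier session.  By
  construction n_distinct = 1 + sum(novelty flags).
* **Gower distances.** Within each session, participants' response sets form
  a categorical participants x items matrix; for purely categorical rows the
  Gower distance reduces to the proportion of mismatching items, computed
  over mutually non-missing items (n compared recorded).  All unordered
  pairs are emitted; with 22 participants in sessions 1-4 and 20 in the
  fifth, that is 4 x 231 + 190 = 1,114 distances.
* **Pronunciation frequencies.** Per (item, pronunciation, session), how
  many participants used it, zero-filled across sessions so disused
  pronunciations show 0.  The final session can be excluded (default in the
  pipeline) because fewer participants completed it.

## Mixed-effects analyses

Five stages, run over those tables:

1. One-sample t tests of per-participant and per-item mean distinct counts
   against 1 (the no-variability value).  A vector that is exactly all ones
   returns t = 0 rather than an error; zero variance away from 1 is an error.
2. `diversity ~ consistency * literacy + (1|item) + (1 + consistency|participant)` (LMM, REML).
3. `novel ~ session * consistency + session * literacy + consistency * literacy + (1|participant) + (1|item)`
   (binomial GLMM, logit link, session centred).
4. `distance ~ session_z + (1 + session_z|participant_a) + (1 + session_z|participant_b)`
   (LMM with two crossed slope terms; session standardised).
5. `frequency_c ~ 1 + (1 + session|pronunciation)` on the zero-filled,
   then centred frequency table (sessions 1-4); each pronunciation's
   conditional intercept and slope (fixed effect + BLUP) are extracted and
   their Pearson correlation summarises whether frequent pronunciations
   spread while rare ones drop out.  Zero-filling precedes centring; session
   is left on its 1..4 scale there (configurable), since the correlation of
   interest is between levels and trends, not the intercept location.

The literacy covariate is the mean of within-sample z-scored spelling and
vocabulary scores (centred by construction); participants missing a score
are excluded with a warning.

**Estimation engine.** The models are fit by the package's own engine
(`nonwordvar.mixed`), because the required structures — crossed grouping
factors each with correlated random intercepts and slopes, Satterthwaite
degrees of freedom, and a Laplace-quality binomial fit — are not jointly
available in the installed Python stack.  Linear models optimise the
profiled REML deviance over the relative Cholesky factors of the
random-effect covariance blocks (fixed effects, conditional modes and the
residual variance all have closed forms given those factors); a
block-diagonal fast path handles single-factor models.  Satterthwaite df
come from finite-difference gradients of each coefficient's variance with
respect to the variance parameters, combined with the observed information
of those parameters.  The binomial model maximises the Laplace
approximation (inner Newton for the conditional modes, log-determinant
correction), started from a beta-profiled fit and polished over all
parameters; Wald z tests use the numerical Hessian.  The engine is verified
three independent ways in the test suite: live against statsmodels MixedLM
where that model class overlaps, against the closed-form REML components of
a balanced one-way design, and against frozen reference fits produced once
with lme4/lmerTest/glmer (agreement ~1e-5 on coefficients, df matching to
the printed precision; tolerance 1e-3 asserted).

**Maximal-feasible random effects.** Each LMM stage tries the full stated
structure, then the same with random-effect correlations dropped, then
random intercepts only; the applied fallback is recorded in the result and
the run manifest.

**Variance explained.** Marginal and conditional R2 follow the
fixed-vs-total variance decomposition for mixed models, with random-slope
terms contributing their observation-averaged quadratic form.  For the
binomial model both the theoretical latent residual variance (pi^2/3) and
the delta-method variance (1/(p(1-p)) at the mean fixed-effect linear
predictor) are reported.  Semi-partial R2 for a term is the drop in
marginal R2 when the term and all interactions containing it are removed
and the model refit.

## Synthetic data generator

No multi-session nonword corpus is freely redistributable and the English
GPC statistics require a licensed database, so the generator supplies both
sides: lexicons sampled from a known grapheme inventory (so GPC estimates
can be checked against true distributions and converge in total variation
as the corpus grows), and response tables from a mechanistic model of the
settling dynamic:

* Items are disyllabic CVC-CVC nonwords over an inventory with graded
  ambiguity (deterministic consonants up to a three-way vowel); an item's
  true consistency is the entropy of its most inconsistent syllable under
  the generating distributions.
* Each participant's knowledge of an item is a Dirichlet perturbation of
  the item's population pronunciation distribution with concentration
  kappa = 8 (the product over its graphemes' distributions); literacy can
  couple to kappa multiplicatively (default 0 — the motivating data showed
  no literacy effect).
* Across sessions a knowledge-weighted Pólya urn governs repetition: at
  session t each past response token carries weight alpha(t) times the
  participant's knowledge probability of that response, against unit weight
  on a fresh draw from knowledge.  Weighting reinforcement by knowledge is
  what lets idiosyncratic early draws be pruned instead of locked in; a
  plain urn preserves the session-1 response distribution and produces no
  across-participant convergence.  The default schedule
  alpha = (0, 4, 6, 8, 10) was calibrated once so the default configuration
  sits inside its contract band — mean distinct pronunciations per
  participant x item in [1.3, 2.0] (observed ~1.6) with declining novelty
  and shrinking inter-participant distances — and is not otherwise tuned.
* Design defaults: 22 participants x 50 items x 5 sessions, the last two
  participants missing the final session.

What the generator does **not** emulate: transcription error, phonetically
graded similarity between responses (all differences are categorical),
reaction times, item-order or fatigue effects, and any participant-level
heterogeneity beyond the kappa/literacy draws.  Passing tests therefore
show that the pipeline measures what it claims on data with the assumed
structure, not that the mechanistic model is the true account of human
settling behaviour — it is one testable concretisation of a noisy-knowledge
account.

**Calibration and nulls.** The urn mechanism has no true null for some
effects (novelty declines mechanically whenever the response support is
finite), so estimator calibration uses parametric generators that simulate
from each stage's own equation at the design size: strong-effect runs score
sign recovery, bias, RMSE and 95% CI coverage of the generating
coefficient; null runs (coefficients set to 0) pool the p values of every
null term to check type-I error.  The urn generator is used for end-to-end
sign recovery and for the emergent-phenomena suite (novelty strictly
decreasing, distances shrinking, across 100 seeds).  A `decouple_consistency`
switch reassigns generating distributions across items at random, providing
a true null for the consistency effect while leaving the measured covariate
intact.

**A note on stage 5.** The intercept-slope correlation computed from
conditional modes saturates toward the estimated random-effect correlation
(and toward 1) when per-pronunciation slope information is weak, a standard
shrinkage phenomenon reproduced identically by lme4 on the same data.  The
generator's frequency tables are in that regime, so the suite tests the
sign and the recovery of the generating correlation parameter, not the
magnitude of the BLUP correlation.

## Numerical choices and limitations

* Entropy is in nats throughout (natural log), matching the defining
  formula of the consistency and diversity measures.
* Optimisation: Nelder-Mead with bounds on the Cholesky diagonals for LMM
  theta (dimension ≤ 6 here); profiled start plus L-BFGS-B polish for the
  GLMM.  Objectives return a large finite penalty on non-positive-definite
  iterates; the penalized residual sum of squares is floored to guard
  perfectly fitting (degenerate) inputs.
* Boundary fits (singular random-effect covariances) are returned as-is,
  as reference implementations do; the fallback ladder only engages on
  non-convergence or errors.
* Satterthwaite df fall back to the residual df when the information matrix
  is not invertible.
* Ties in rule specificity are broken by inventory file order, making
  parses deterministic but inventory-order-dependent when two equally
  specific rules match; the bundled inventory has no such ties.
* The syllabification fallback is a deliberately simple rule; for real item
  sets the manual overrides file is the intended path, mirroring hand
  syllabification of experimental items.
* Problem sizes in the test and acceptance suites are the design size
  (22 x 50 x 5) with 25 replicates for the calibration suites and 100 seeds
  for the emergent-phenomena suite; the replicate counts are the package's
  chosen defaults and scale up by argument.
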