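# Methods

This note documents the modelling assumptions, parameter conventions,
numerical choices and limitations of `morphcomp`.  Nothing here reports
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Derivation trees and the lexicon dialect

A word's morphological analysis is a labelled tree over morphemes with
syntactic-category node labels (N, V, A, B by default, extensible).
Affixes are terminal children of the node they head — prefixes on the
left, suffixes on the right — and zero conversion is a unary node
(`(N (V walk))`).  Binary nodes must pair exactly one affix terminal
with one subtree; compounds (two non-affix children) are outside the
dialect and are rejected at parse time, leaving the entry loaded but
tree-less.

The on-disk format is a TSV (`word freq status flags struclab`) with
bracketed structure strings (`((teach)[V],(er)[N|V.])[N]`).  The part of
an affix label after `|` (its subcategorization) identifies which child
is the affix during parsing and is otherwise not used: classification
and rule extraction rely only on the resulting categories.  Exclusion
flags (`StrucAllo`, `StrucSubst`, `StrucOpac` — stem allomorphy,
orthographic substitution, semantic opacity) are carried as a set; the
*stimulus* stage filters on them, the reader and the model trainers do
not, so models can be trained on the full lexicon while stimuli are
built only from transparently decomposable words.

## Stimulus construction

Structure templates are extracted per outer affix from trimorphemic
words of the requested kind: the (outer, inner-suffix) combination with
the highest type frequency wins, provided it clears the threshold
(default 5 word types for linear suffix-suffix structures, 2 for nested
prefix-suffix structures — nested types are an order of magnitude rarer)
and the outer affix is in the productive set.  The productive inventories
are configuration data; the shipped defaults are ten outer suffixes
(*al, ity, ship, er, ize, ally, ly, ness, ist, ism*) and eight prefixes
(*pre, sub, super, inter, over, non, de, un*).  Ties on type frequency
break lexicographically by inner affix so extraction is independent of
lexicon order.

Stems are bimorphemic suffixed words whose inner suffix, middle and
root categories match the template and whose token frequency is ≥ 20
(familiar stems; the point of the stimuli is an unfamiliar whole, not an
unfamiliar part).  Generation alternates word-by-word between the two
kinds, cycles templates round-robin within a kind, and samples stems
without replacement.  A candidate is rejected if its adjusted surface is
attested in the lexicon, blocklisted, a duplicate surface, or reuses a
root — root uniqueness is enforced globally across both kinds to rule
out repetition priming.  Orthographic junctions are data, not code: an
ordered rule table whose defaults are final-*e* deletion before a
vowel-initial suffix (*observe + able → observable*) and *y → i* before
a non-*i* suffix (*happy + ness → happiness*); prefixes concatenate
unless a prefix-side rule is supplied.  Semantic selectional
restrictions are deliberately not controlled.

List construction distributes the stimuli into `n_lists` randomized
lists balanced by kind and appends each list's reversal, doubling the
list count; with the default design (600 words, 6 lists) this yields
12 lists of 100 words, 50 per kind.

## The five models

All models are trained by token-weighted relative-frequency estimation:
a word's counts are multiplied by its corpus token frequency, with
zero-frequency types contributing a floor weight of 1 (configurable) so
rare attested words are not erased.  All conditional distributions are
Lidstone-smoothed with α = 0.1 (configurable; α applies to every
distribution — transitions, emissions, rules — since the source
procedure does not single any out).

**Bigram Markov models** (characters / syllables / morphemes) score a
word as the product of adjacent-unit transitions delimited by BOS/EOS
sentinels, so word length is part of the probability.  The smoothing
vocabulary for every context is the observed unit types plus EOS plus a
single UNK type; unknown units at test time map to UNK.  With one
training word *ab* of weight 1, P(a | BOS) = (1+0.1)/(1+0.1·4): the
vocabulary is {a, b, EOS, UNK}.

**The HMM** is trained supervisedly on category-tagged morpheme strings
read off the trees (an affix is tagged with the category it derives, the
root with its own category).  Transition rows are smoothed over
tags + EOS, emission rows over morpheme types + UNK.  Scoring
marginalizes over all tag paths with the forward algorithm in log space
(log-sum-exp), which the tests verify against exhaustive path
enumeration.

**The PCFG** has head-lexicalized rules of four shapes — suffixation
`X → Y s`, prefixation `X → p Y`, zero conversion `X → Y`, root
insertion `X → m` — with a single conditional distribution per left-hand
side covering all its right-hand sides, smoothed over the observed
right-hand sides plus one unseen-root event per category.  Novel roots
thus receive UNK-root mass, while an unattested affix combination is a
structural zero: a word whose affix skeleton licenses no parse scores
−∞ and is flagged, which is a different situation from "parseable but
improbable".  Scoring sums over all parses with an inside chart over
morpheme spans; unary chains are closed exactly by solving
(I − U)x = b per span, where U is the unary-rule matrix — a geometric
series that is finite whenever α > 0 because every category reserves
unseen-root mass.  The start symbol is a smoothed categorical over the
root-node categories of the training trees.  Inside values are computed
in linear space: words here are at most a handful of morphemes, far from
underflow.

**The unigram** over morphemes (types + UNK, no sentinels) is the SLOR
reference distribution, trained with the same weighting and smoothing.

The syllabifier is deliberately orthographic, not phonemic: nuclei are
maximal vowel-letter runs (*y* is vocalic unless a plain vowel follows)
and intervocalic clusters split by onset maximization against a legal
onset inventory, either a stock English list or one induced from the
training lexicon's word-initial clusters.  It is pluggable — any
callable from word to syllable list can replace it, so pre-syllabified
(e.g. phone-based) input can be used where available.

## SLOR

`SLOR = (log p_w − log p_m)/|ζ|` with natural logs.  The default length
convention sets |ζ| to the morpheme count for *all* models: the
normalizer is then constant across models for the same word (all
stimuli are trimorphemic, |ζ| = 3), so between-model differences
reflect structure, not unit granularity.  The genuinely defensible
alternative — per-model unit counts (characters for the character
model, etc.) — is implemented as `length_convention="model_units"`.
`p_m` is always the morpheme unigram, including for character and
syllable models, as the measure's definition requires.

## Judgment simulation

The simulator mirrors the analysis model: the latent response of
participant *p* to word *w* at list position *o* is

    y = intercept + β·score(w) + u_p + u_w + u_o + ε

with independent mean-zero normal intercepts and residual, discretized
to 1–7 by fixed cut-points (−1.5, −0.9, −0.3, 0.3, 0.9, 1.5 — fixed
rather than adaptive so β means the same thing across runs).  Word
scores are z-scored before entering the latent model
(`standardize_scores=True`), putting β in residual-SD-per-score-SD
units regardless of the score scale.  Defaults: 180 participants, 6
lists (plus reversals, so 12), β = 0.5, random-intercept SDs 0.3
(subject), 0.2 (word), 0.1 (order), residual SD 1 — a moderate,
word-noise-dominated-by-residual regime typical of single-item Likert
tasks.  Incomplete trials (missing ratings) can be planted, and the
participant-metadata generator plants the exclusion triggers (5
non-native speakers + 9 foreign-born of 180) that the preprocessing
stage must catch.

The synthetic lexicon generator samples word types from a known PCFG
(`GroundTruthGrammar`) whose affix rules realize the ten linear and
eight nested target structures over three disjoint root inventories
(600 roots each for N, V, A; B is affix-derived only), and assigns the
type at collection rank *r* frequency `round(f_max · r^−s)` (defaults
f_max = 10⁶, s = 1) — corpus-scale Zipf mass so that the ≥ 20 stem
threshold retains most bimorphemic types, as it would in a real lemma
corpus.  About 30% of entries receive a random exclusion flag, matching
the attrition a real morphological annotation imposes.  A second
sampling mode (`sample_lexicon_tokens`) draws an i.i.d. token stream
and keeps empirical counts; this is the regime in which token-weighted
rule frequencies provably converge to the generating probabilities, and
it is what the parameter-recovery tests use.  What the generator does
*not* emulate: English orthotactics and phonology, semantic structure,
homography, inflection, and the fine shape of real frequency spectra
beyond the Zipf profile — so passing tests demonstrate the pipeline's
statistical machinery, not coverage of natural-language idiosyncrasy.

## Evaluation

Preprocessing removes excluded participants' trials, then incomplete
trials, then z-scores ratings within participant (SD with one delta
degree of freedom; a zero-variance participant gets z = 0 with a
warning).

Group contrasts use per-word mean ratings/scores as the unit of
analysis, not raw trials: with *n* words per group, t = d·√(n/2), which
is the scale on which word-level effect sizes and t statistics are
mutually consistent (trial-level n would inflate t several-fold).
Cohen's d uses the pooled SD with Bessel-corrected group variances;
the t test is Student's pooled-variance two-tailed test.

The mixed model is `z_rating ~ 1 (+ slor) + (1|subject) + (1|word) +
(1|order)` where *order* is the within-list presentation position,
fitted by maximum likelihood (never REML) so deviances are comparable
across the nested pair.  The fitter profiles out the fixed effects and
the residual variance analytically and optimizes only the variance
ratios γ_k = σ_k²/σ², using the Woodbury identity on the sparse
random-effects design: each objective evaluation is one Cholesky
factorization of a q×q matrix (q = total random-effect levels, ≈ 870 at
full design scale, < 1 s per fit).  γ is optimized on the log scale
(bounds e⁻¹² to e⁶) with L-BFGS-B from two starts (0.1 and 0.5), best
result taken, with a Nelder-Mead rescue pass if neither start reports
convergence — the log parametrization removes the boundary pathology
that makes raw-scale quasi-Newton steps stall, and the tests pin the
resulting deviances against an independent variance-components
implementation to ~1e−2.  Conditional residuals are observed minus
fitted including predicted random effects; fixed-effect covariance is
the profiled GLS covariance (variance-parameter uncertainty is not
propagated, the usual ML convention).

Deviance accuracy compares base and target deviances with a χ²(df = 1)
likelihood-ratio test; a negative drop beyond 1e−4 raises a convergence
warning, and comparisons involving non-converged fits are refused.
Pairwise between-model comparisons are reported as deviance differences
with the same χ²(1) reference but flagged as heuristic: two target
models are not strictly nested.

Residual accuracy uses per-word *means of conditional residuals*,
|ε_base(w)| − |ε_target(w)| summed over words, with per-affix sums and
per-kind values that average the affix sums within each structure kind.
Because the baseline already carries a by-word random intercept, its
conditional per-word residuals are shrinkage leftovers; a target whose
SLOR explains word-level variance *reduces* the fitted word variance,
strengthens shrinkage and can therefore show negative RA totals even
when its deviance accuracy is best.  RA is accordingly a per-word
diagnostic of where a model helps or hurts relative to baseline, not a
ranking statistic; the residual type behind the original figure is not
stated in the source, and this convention is ours.

## Problem sizes used by the test suite

The acceptance tests run the pipeline at sizes chosen to exercise every
mechanism while keeping the suite quick: a 3,000-type lexicon with 120
stimuli and 24 simulated participants for the end-to-end metric-recovery
replicates; 120,000 sampled tokens for PCFG parameter recovery (max
absolute rule-probability error ≤ 0.02); 120 words × 20 participants for
slope recovery, a size at which profiled-ML standard errors are close to
nominal (at 60 words their small-sample downward bias makes 2-SE
coverage marginal); and the full published design (180 participants,
600 words, 12 lists) for the attrition arithmetic, where no model
fitting is needed.

## Known limitations

* The syllabifier is orthographic; its syllable inventory differs from a
  phone-based one, so syllable-model probabilities are not comparable to
  phonemic implementations.
* Likert responses are modelled linearly on z-scores, not with an
  ordinal link; cut-point information is discarded after simulation.
* Discretization plus per-participant z-scoring attenuates the latent
  slope, so fitted β on z-ratings is not numerically equal to the
  simulator's β (slope-recovery tests therefore operate on the
  continuous response; winner-selection tests use the full discretized
  chain, which preserves ordering).
* The PCFG start distribution and the per-category UNK-root mass are
  pragmatic conventions; with α = 0 the model degenerates to pure MLE
  and unseen material scores −∞.
* Pairwise model DA comparisons are heuristic (non-nested models).
* The stimulus generator guarantees orthographic well-formedness only
  through the junction-rule table; it has no notion of phonotactic or
  semantic plausibility.
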