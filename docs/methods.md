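# Methods

`pluralcue` measures, per individual speaker, how strongly grammatical
gender conditions German plural-class production, and tests competing
accounts of that conditioning with simulation-calibrated Bayesian model
comparison. This note records the models, the defaults and why they are what
they are, the numerical choices, and the limits of what the synthetic data
can show.

## Variables and information measures

Plural class `C` is a six-way category defined by the plural suffix: -(e)n,
-e, null, -s, -er, and a catch-all "other" (umlaut alternations are
disregarded, so an umlaut-only plural belongs to the null class). Gender `G`
is feminine/masculine/neuter. For a speaker's productions (or a lexicon
stratum) summarized as a gender-by-class table, the package computes

- `H(C) = −Σ_c P(c) log2 P(c)` — plural-class entropy, bits;
- `H(C|G) = Σ_g P(g) H(C|G=g)` — conditional entropy, bits;
- `MI(C;G) = H(C) − H(C|G)` — mutual information, "gender conditioning";
- `MI/H` — normalized conditioning, the share of class variation attributable
  to gender, in [0, 1], defined as 0 when `H(C) = 0` (no variation, so none
  of it can be conditioned).

All estimation is plug-in (maximum likelihood) from observed counts with the
`0·log 0 = 0` convention. Plug-in MI is upward-biased at the experiment's
sample size (24 productions per speaker), which is deliberate: the
hypothesis test never compares a speaker to "MI = 0" but to the simulated
distribution of plug-in MI under a gender-ignoring regime, which carries the
same bias. Bias-corrected estimators are therefore intentionally absent.

KL divergence (`kl_divergence`) supports item-level comparison of plural
distributions; both arguments receive additive smoothing (default `1e-6`)
with renormalization, because reference distributions can have zero cells on
the comparison's support. Base 2 by default, consistent with everything else.

## Lexicon tables

CELEX-derived percentage tables are packaged exactly as published: the
gender-conditional class percentages for the full noun lexicon and for
monosyllables, and the corresponding gender marginals (42/38/20 and
13/64/23). Cells are integers as printed and divided by 100 at the point of
use; two monosyllable rows sum to 101 and 99 from rounding, and are
normalized per row at table construction. The pooled "all genders" row is
used directly as its own distribution `p_All`, not recomputed as a mixture.

Because only rounded percentages are published, the exact-count values
`MI = 0.67` and `H(C|G) = 1.31` bits for the full lexicon are not exactly
recoverable: the packaged tables yield 0.70 and 1.28. The monosyllable
characterization (H ≈ 1.73, MI ≈ 0.29, MI/H ≈ 0.17) and the pooled entropy
(1.99) agree with the published 1.71/0.30/0.17 and 1.98 at print precision.

## Generative regimes and simulation

Each simulated participant produces 24 plural classes. Three regimes:

- **h0 (gender-ignoring):** every class drawn i.i.d. from `p_All`;
- **h1 (lexicon-level conditioning):** classes drawn from the full-lexicon
  gender rows;
- **h2 (monosyllable-mediated conditioning):** classes drawn from the
  monosyllable-stratum rows.

Two designs: **fixed-gender** (8 items per gender, the counterbalanced
presentation design) and **sampled-gender** (the participant assigns gender:
gender counts ~ Multinomial(24, p_G), then classes per gender). For the
sampled design, h0/h1 default to the full-lexicon gender marginal and h2 to
the monosyllable marginal (monosyllables have a markedly different gender
mix, and speakers' self-assigned genders resemble it); either marginal can
be passed explicitly, since which one belongs to the mediated regime in the
self-assignment design is genuinely open.

Per-participant summaries use the speaker's own empirical gender counts as
`P(g)` (uniform 8/8/8 under the fixed design; a sampled gender with zero
items contributes nothing to `H(C|G)`). Draw order is fixed — genders first,
then classes in F, M, N order — so cohorts are bit-reproducible per seed.

## Beta-regression hypothesis models

For participant *i* with entropy `H_i` and response `y_i = (MI/H)_i`:

    y_i ~ Beta(μ_i φ, (1 − μ_i) φ),   μ_i = logit⁻¹(β0 + β1 H_i)

with priors `β0 ~ Normal(−0.5, 0.5)`, `β1 ~ Normal(0, 0.1)`,
`φ ~ Gamma(5, 1)` — weakly informative, calibrated so the prior predictive
stays off the 0/1 boundaries. Under h0 the slope is positive (more variation
means more noise MI to "explain"); under real conditioning it is negative
(structure diluted by variation). One model is fitted per regime on a
10,000-participant simulated calibration cohort.

**Boundary handling.** The Beta density is undefined at y ∈ {0, 1}, which
h0 simulants occasionally hit exactly. For fitting, responses are squeezed
with `y' = (y(n−1) + 1/2)/n` (n = cohort size); for scoring single
participants the ratio is clamped to `[1e-4, 1 − 1e-4]`. Both are
configurable; at n = 10,000 the squeeze's effect on the coefficients is
below 0.03.

**Sampling.** The posterior over `(β0, β1, log φ)` is sampled with the
affine-invariant ensemble sampler using differential-evolution proposals
(80% DE, 20% snooker); defaults are 32 walkers × 2,000 retained steps after
1,000 warmup. Sampling runs in a centered-covariate basis
(`c0 = β0 + β1·H̄`), where the posterior is nearly spherical, and draws are
mapped back; the stretch move on the uncentered ridge mixed an order of
magnitude slower. The likelihood is evaluated on unique `(H, y)` pairs with
multiplicities, which collapses a 10,000-participant cohort to a few
thousand rows. Convergence gates: split-R̂ ≤ 1.01 and bulk ESS ≥ 400 per
parameter, walkers treated as chains; failing fits are returned flagged with
a warning (the pipeline refuses to classify with them).

**Per-participant evidence.** A participant's log predictive density under a
fitted model is `log mean_draws Beta(y | μ(H; β), φ)` — the posterior
predictive, not a plug-in at posterior means (plug-in is available as a
mode). `log BF10 = log p(y|h1) − log p(y|h0)`; the best-fit label is the
argmax over fitted models, ties breaking toward h0 (parsimony). Cohort-level
evidence is the summed log BF; its exponential underflows to 0 for strongly
negative sums and is displayed as 0 below 1e-12.

## Synthetic behavioral cohorts

Real participant data from the elicitation experiments are not public, so a
generator emulates the designs: 24 novel monosyllabic noun stimuli;
fixed-design gender counterbalanced over three lists (every item carries
each gender in exactly one list); self-assignment design drawing gender per
item (default marginal: monosyllables). Each synthetic participant follows a
latent strategy drawn from a mixture — gender-ignoring, lexicon-level,
monosyllable-level, or a deterministic "super-lexical" rule (feminine →
-(e)n, else -e). Raw plural strings are rendered by suffixation ("other" is
rendered "-se", an out-of-class token chosen only to round-trip through the
classifier) and classified back by longest-suffix-first matching after
umlaut normalization; "-n" after a stem-final -e counts as -(e)n.

What the generator does *not* emulate: item-specific phonological attraction
(real speakers' analogies to particular neighbors), typos and creative
responses, and within-participant strategy drift. Passing pipeline tests on
synthetic cohorts therefore validates the machinery (classification,
summaries, Bayes factors, mixture recovery), not any claim about real
speakers.

## Orthographic neighborhoods

Neighbors of a stimulus are lexicon entries with normalized Levenshtein
distance ≤ 0.5. Distance is plain edit distance (insert/delete/substitute,
computed on Unicode strings so umlauted letters are single symbols),
case-folded but umlaut-preserving; normalization divides by the stimulus
length by default ("length of the word" is ambiguous; dividing by the longer
spelling is available as `norm="max"`, and the neighbor sets differ at the
margin). Exact spelling matches of the stimulus are excluded. An empty
neighborhood is reported as an explicit signal, never as zero MI. The
package ships only a small toy lexicon; the published CELEX-wide average
(gender explaining ~41% of neighbor class variation) requires CELEX and is
out of scope.

## Problem sizes and runtime choices

Calibration fits run at the study's 10,000 participants per regime (about
90 s per fit on one CPU). The test suite fits smaller cohorts where the
property under test allows it: parameter-recovery replicates at n = 5,000
with a lighter sampler configuration (16 walkers, 500 + 500 steps),
sign-constraint fits at n = 3,000. Parameter recovery follows
simulation-based calibration: truths are drawn from the priors, data from
the likelihood, and 95% interval coverage is counted across 20 replicates.

## Known limitations

- Reproduction of the published calibration coefficients is limited by the
  printed inputs: the intercept/slope pair for the null fixed-design fit
  centers near (−2.46, 0.40) from the packaged rounded tables against the
  published (−2.58, 0.46); the sampled-design and monosyllable fits
  reproduce to ±0.05. The published posterior standard errors (0.01) are
  also sharper than 10,000 Beta observations support (~0.04), so the
  original calibration inputs evidently differ in detail from what is
  printed.
- The classifier for raw plural strings makes package-level decisions the
  original study never specified (umlaut-only → null class, rule order);
  anyone comparing against original raw data should review them.
- Ensemble-sampler R̂ treats coupled walkers as chains, which is slightly
  anticonservative; the gate is compensated by requiring large ESS.
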