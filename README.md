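# pluralcue

Per-speaker information-theoretic analysis of grammatical gender as a cue in
German plural-class production.

## The problem

Every German noun carries a grammatical gender (feminine/masculine/neuter)
and a plural class, defined here by its plural suffix: *-(e)n*, *-e*, null,
*-s*, *-er*, or other. In the lexicon, gender is a strong statistical cue to
plural class. Whether individual speakers actually *use* that cue when
inflecting novel nouns is an empirical question, and answering it per
speaker takes more than a group-level significance test: a pooled effect can
be driven by a handful of gender-sensitive speakers while the median speaker
ignores gender entirely.

`pluralcue` implements the full analysis pipeline for that question, aimed
at researchers in psycholinguistics and cognitive modeling:

- **Information measures** (`pluralcue.infotheory`): plug-in Shannon entropy
  `H(C)`, conditional entropy `H(C|G)`, mutual information `MI(C;G)`, the
  normalized conditioning ratio `MI/H ∈ [0,1]`, and smoothed KL divergence,
  all in bits.
- **Lexicon tables** (`pluralcue.lexicon`): packaged published gender ×
  plural-class percentage tables for the full German noun lexicon and for
  monosyllables, with gender marginals.
- **Hypothesis simulators** (`pluralcue.simulate`): cohorts of simulated
  speakers producing 24 plural classes by multinomial sampling under
  competing regimes — gender-ignoring (`h0`), lexicon-level conditioning
  (`h1`), monosyllable-mediated conditioning (`h2`) — in both the
  fixed-gender (8 items per gender) and self-assigned-gender designs.
- **Bayesian model comparison** (`pluralcue.bayes`): for each regime, a Beta
  regression of `y = MI/H` on `H` with logit link, `y ~ Beta(μφ, (1−μ)φ)`,
  `μ = logit⁻¹(β0 + β1 H)`, priors `β0~N(−0.5,0.5)`, `β1~N(0,0.1)`,
  `φ~Gamma(5,1)`, fitted by ensemble MCMC on a 10,000-speaker simulated
  calibration cohort; individual speakers are then scored by posterior
  predictive density and compared across regimes by log Bayes factors.
- **Synthetic behavioral cohorts** (`pluralcue.synthdata`): per-trial
  production records (raw plural strings included) for mixtures of
  production strategies under the real experimental designs, plus the
  plural-string classifier — the original participant data are not public,
  so this module makes the pipeline testable end to end.
- **Orthographic neighborhoods** (`pluralcue.neighbors`): normalized
  Levenshtein neighbor retrieval (threshold 0.5) and neighborhood-level
  gender-conditioning statistics.
- **Orchestration and CLI** (`pluralcue.cli`): a `pluralcue` command with
  `simulate`, `fit`, `synth`, `classify`-style verbs and a one-config
  end-to-end pipeline.

See `docs/methods.md` for the models, assumptions, and numerical choices.

## Worked example

Information content of the packaged lexicon tables:

```python
from pluralcue import builtin_tables, info_summary

t = builtin_tables()
for name, tab in [("overall", t.overall), ("monosyllables", t.monosyllable)]:
    i = info_summary(tab)
    print(f"{name:14s} H(C)={i.entropy_bits:.2f}  MI(C;G)={i.mi_bits:.2f}  MI/H={i.ratio:.2f}")
```

```
overall        H(C)=1.98  MI(C;G)=0.70  MI/H=0.35
monosyllables  H(C)=1.73  MI(C;G)=0.29  MI/H=0.17
```

Gender explains about a third of plural-class variation lexicon-wide, but
only ~17% among monosyllabic nouns (the stratum novel-noun stimuli belong
to). Now simulate gender-*ignoring* speakers and fit the null calibration
model:

```python
import numpy as np
from pluralcue import hypothesis_spec, simulate_cohort, fit_beta_regression, posterior_summary
from pluralcue.bayes import MCMCConfig

cohort = simulate_cohort(hypothesis_spec("h0"), 10_000, seed=1)
print(f"median MI/H = {np.median([s.ratio for s in cohort]):.3f}")
post = fit_beta_regression(cohort, mcmc=MCMCConfig(seed=1), hypothesis="h0")
print(posterior_summary(post))
```

```
median MI/H = 0.145
       Estimate  Est.Error  l-95% CI  u-95% CI
beta0     -2.47       0.04     -2.54     -2.40
beta1      0.40       0.02      0.36      0.44
phi       31.47       0.45     30.59     32.36
```

Even speakers who ignore gender completely show a median *apparent*
conditioning of ~14% — the small-sample bias of plug-in mutual information
at 24 productions — and that noise grows with the speaker's entropy
(`beta1 > 0`). This is exactly why per-speaker hypothesis testing calibrates
against a simulated null rather than against zero. Fitting the same model to
an `h1` (lexicon-conditioned) cohort flips the slope negative; a real or
synthetic participant's `(H, MI/H)` is then scored under both fitted models
and the difference in log predictive density is their log Bayes factor.

The same pipeline from the shell:

```sh
pluralcue simulate --hypothesis h0 --n 10000 --seed 1 --out h0_cohort.csv
pluralcue fit --cohort h0_cohort.csv --hypothesis h0 --seed 1 --out h0_post.csv
pluralcue synth --experiment exp1 --n 100 --mix 0.85,0.10,0,0.05 --seed 2 --out records.csv
pluralcue report --experiment exp1 --out-dir out/
```

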