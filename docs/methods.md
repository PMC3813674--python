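# Methods

## Belief model

Syntactic expectations are modelled as a Dirichlet–multinomial over three
structure categories: main-verb continuation (MV), reduced relative clause
(RC), and OTHER, which absorbs all remaining continuation types. A
three-category model is used rather than a two-outcome beta-binomial
because MV and RC do not exhaust the probability mass (p(MV) = .7 and
p(RC) = .008 sum well below 1); carrying OTHER explicitly preserves the
key competition property — evidence for RC drains probability from MV —
while matching the corpus prior probabilities exactly.

Prior pseudocounts are α₀ · p₀(c). Each *critical* sentence read adds one
pseudo-observation to its structure category at sentence offset; fillers
contribute no MV/RC evidence (they are constructed to avoid the ambiguity
entirely), although an option exists to count them as OTHER evidence.
Belief updating is per item, not per word: the trajectories the model
predicts are indexed by item order, and word-level incremental parsing is
out of scope.

Surprisal is −log₂ p, in bits, fixed by the reference value
−log₂(.008) ≈ 6.97. Trajectories record the query category's predictive
probability and surprisal *before* each evidence event, so categories
absent from a block still have a defined, evolving trajectory.

### Prior strength α₀

α₀ is the model's only free parameter. The default is 1.0 (a very weak
prior: a single observed sentence carries as much weight as all prior
experience). `calibrate_alpha0` fits α₀ by least squares (in bits) to four
published illustrative trajectory summaries for the two designs
(Block-3-onset MV surprisal and Block-3 means for both groups of the
blocked design, plus the grand-mean MV surprisal of the interleaved
design). The best single-α₀ fit is ≈ 3.3 with substantial residual error
(SSE ≈ 0.65 bits²); this is expected, because the published onset figure
(3.99 bits for p ≈ .019) is not internally consistent with base-2
surprisal (−log₂ .019 = 5.72; −ln .019 = 3.96). The calibration therefore
*documents* the best fit and reports the onset surprisal in both bases
rather than asserting any of the printed values. The α₀ = 1 default is
retained for all generation and prediction.

### Canonical evidence sequences

Predicted trajectories use idealized evidence orders: the interleaved
design alternates RC and MV strictly (18 each, RC first), matching its
balanced statistics without the sampling noise of a particular shuffle;
the blocked design uses its deterministic block order (16 RC / 10 RC /
10 MV for the RC-First group, with the Filler-First group's Block 1 empty
of evidence). Block means are means of the per-event trajectory values
within a block.

## Surprisal→RT link

Predicted disambiguating-region RT is `rt_intercept + rt_slope ×
surprisal`; the predicted ambiguity effect is `rt_slope ×
surprisal(p(structure)) − unambig_offset`. The unambiguous-condition cost
is a constant offset (default 0): only the expectation violation in the
ambiguous condition is modelled. All link magnitudes are fixture
conventions — the default 20 ms/bit is round and of plausible magnitude
for self-paced reading, but nothing in the package estimates it from
data, and no conclusion depends on it.

## Synthetic data generator

The generator emulates word-by-word self-paced reading for both designs:

- **Designs.** Interleaved: 36 critical items (18 RC / 18 MV, half of
  each ambiguous) + 50 fillers, four counterbalancing lists. Blocked: 71
  stimuli over three implicit blocks (RC-First: 16 RC / 10 RC + 20
  fillers / 10 MV + 15 fillers; Filler-First replaces Block 1 with 16
  fillers), two lists per group, 40 subjects per group by default;
  interleaved default is 72 subjects.
- **Counterbalancing.** All lists of a design share one seeded
  presentation order; only the condition (version) assignment rotates
  across lists. Every stimulus position therefore hosts each condition in
  exactly one list, making condition exactly orthogonal to position —
  the point of item rotation. (With per-list shuffles and only 2–4
  lists, ambiguity would be confounded with stimulus position, which
  biases the block analyses that — deliberately, following the analysis
  conventions — carry no stimulus-order covariate.)
- **Sentence templates.** Critical sentences have 4 regions of 3/4/3/1
  words (preamble / ambiguous region / disambiguating region / final
  word); fillers are 8–14 words of a single `filler_body` region. Word
  lengths are drawn per word from a seeded discrete distribution on 2–12
  characters, fixed per list (the same "sentences" for every subject in
  a list); real lexical content is not rendered — length is a nuisance
  regressor only.
- **RT model.** Word RT = subject baseline (Normal around
  `rt_intercept`, SD 50 ms) + subject length slope (Normal, 12 ± 4
  ms/char) × word length + `task_adapt_coef` (−20 ms) × log stimulus
  order + region cost + Gaussian noise (SD 60 ms), truncated at 1 ms.
  The region cost applies to every word of the disambiguating region of
  ambiguous critical trials and equals `rt_slope` × the subject's
  *current* surprisal of the resolved structure; 30% of it spills onto
  the final word (spillover is generated, not modelled). A configurable
  0.5% of words are replaced by out-of-range RTs (uniform on 20–95 or
  2100–3500 ms) to exercise the exclusion rules.
- **Determinism.** One spawned RNG stream per subject (derived from the
  dataset seed), so enlarging the subject count never perturbs earlier
  subjects' data. Noise SDs and the noise model are package choices; no
  published noise model exists for these data.

What the generator does *not* emulate: item-level variability (all items
of a condition are statistically identical), lexically specific (per-verb)
adaptation, spillover dynamics beyond the final word, comprehension
accuracy, and fatigue/attention drift beyond the log-order speed-up.
Passing recovery tests therefore show that the pipeline detects the
modelled adaptation signal at realistic noise levels — not that real
reading data contain no further structure.

## Analysis chain

1. **Exclusion** removes words with raw RT strictly below 100 ms or
   strictly above 2000 ms (boundary values kept); default synthetic data
   lose < 1%.
2. **Length correction** regresses remaining raw RTs on word length with
   a by-subject random intercept and length slope (REML, statsmodels
   MixedLM), over all words — criticals and fillers. Residuals
   conditional on the subject effects are the length-corrected RTs. If
   the mixed fit fails, a per-subject OLS fallback is used with a logged
   warning.
3. **Aggregation** averages residuals per subject × trial × region.
4. **Regressions.** The factorial model regresses disambiguating-region
   residuals on sentence type × ambiguity × item order (all main effects
   and interactions) plus log stimulus order, every predictor
   mean-centered, factors coded ±½.

### Coding conventions

Signs of interaction coefficients depend on factor coding, which differs
between analyses *by design*:

- Full factorial: RC = +½, ambiguous = −½. The sentence type × ambiguity
  interaction (the RC garden-path cost) is then negative and adaptation
  surfaces as a **positive** three-way interaction — the canonical
  description of the effect.
- Simple effects and the two-group analyses: ambiguous = +½ (and
  RC-First = +½, Block 2 = +½), so the ambiguity coefficient *is* the
  garden-path effect and interactions read directly as changes in it: a
  negative ambiguity × item order slope means a shrinking effect; a
  positive ambiguity × group term in the Block-3 analysis means a larger
  MV garden path after RC exposure.

### Random effects

statsmodels MixedLM supports a single grouping factor, so models use
by-subject random intercepts plus random slopes for the within-subject
factors. By-item random intercepts are omitted: the generator injects no
item-level variation, so the item variance component is zero by
construction (an analysis of real data would need crossed random
effects). The backoff ladder on convergence failure is: drop the
item-order slope, then the factor slopes, then fall back to OLS; each
step is logged. When the fixed effects fit the response perfectly
(noise-free data), variance components are unidentified and the fitter
returns the exact OLS solution directly.

Significance uses |t| ≥ 1.96 ⇔ p ≤ .05 with no df correction, the
standard large-sample convention for such models. The continuous
re-analysis of the blocked design's Blocks 1–2 (ambiguity × number of RCs
seen, plus log stimulus order) carries a Bonferroni-adjusted threshold
for its two-test family.

## Numerical and testing choices

- Conjugate updates are exact; the closed form is property-tested to
  1e-12 against a counting oracle.
- Recovery studies use 100 replicates of the 72-subject interleaved
  design for sign recovery and 200 replicates for type-I calibration of
  the focal three-way test; replicate seeds are spawned from a root seed.
  These sizes give binomial standard errors of ~2% on the reported
  rates.
- The acceptance script's sign-recovery study uses 40 replicates, enough
  for a rate with ~3% standard error.
- Degenerate inputs: α₀ ≤ 0, probabilities outside [0, 1] or summing
  above 1, inverted exclusion bounds, empty analysis subsets, unknown
  categories/groups, and rank-deficient design matrices all raise typed
  errors naming the offending quantity.

## Known limitations

- The published human-data coefficients are not reproducible from
  synthetic data and are covered only as sign/structure patterns.
- The belief model is category-level: no per-verb tracking, no
  hierarchical priors over environments, no forgetting/decay — so it
  predicts no long-term or talker-specific modulation.
- The surprisal link is linear by assumption; any monotone link preserves
  the qualitative predictions, but magnitudes are convention.
- The length-correction and factorial models assume Gaussian residuals;
  raw RT distributions in real data are right-skewed, which the Gaussian
  generator sidesteps.
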