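# synadapt

Computational models and analysis pipelines for **rapid syntactic
expectation adaptation** in reading.

When readers repeatedly encounter a syntactic structure that is rare in
everyday language — such as the reduced relative clause (RC) in *"The
experienced soldiers warned about the dangers conducted the midnight raid"*
— the processing penalty it normally incurs (the *garden-path* or
*ambiguity effect*) shrinks, and the penalty for the normally dominant
main-verb (MV) continuation can even grow. `synadapt` implements a belief-
updating account of this adaptation, simulates the two self-paced-reading
experiment designs used to probe it, generates realistic synthetic
word-by-word reading times, and runs the full mixed-model analysis chain —
so the predicted and behavioral signatures of adaptation are reproducible
end-to-end without any human data.

## The model

Expectations over structure categories *c* ∈ {MV, RC, OTHER} are a
Dirichlet–multinomial: prior probabilities *p₀(c)* (corpus values
*p(MV)* = .7, *p(RC)* = .008) are scaled into pseudocounts by a single
concentration parameter α₀, and each critical sentence read adds one
pseudo-observation, giving the posterior predictive

&nbsp;&nbsp;&nbsp;&nbsp;*p(c | data) = (α₀ p₀(c) + n_c) / (α₀ + n)*.

Reading time at the point of disambiguation increases linearly in the
surprisal of the resolved structure, *s(c) = −log₂ p(c)* bits, so the
predicted ambiguity effect is `rt_slope` ms per bit. With a weak prior
(α₀ = 1), RC surprisal starts at −log₂(.008) ≈ 6.97 bits and falls toward
1 bit as RC evidence accumulates, while MV surprisal can rise by at most
~8% of that drop — which is why MV adaptation is nearly invisible in an
interleaved design, and why a blocked RC-heavy design can drive MV
surprisal above RC surprisal (a *reversed* garden path).

## Worked example

```python
import synadapt as sa

prior = sa.PriorConfig()                      # p(MV)=.7, p(RC)=.008, alpha0=1
print(round(sa.surprisal_bits(prior.base_prob_rc), 2))   # 6.97
print(round(sa.max_change_ratio(prior, 0.5), 3))         # 0.081  (< 9%)

# predicted RC-surprisal trajectory across the interleaved design
traj = sa.simulate_trajectory(sa.exp1_evidence(), prior, "RC")
print(round(traj["surprisal_bits"].iloc[0], 2))          # 6.97 on trial 1
print(round(traj[traj.observed == "RC"]["surprisal_bits"].iloc[-1], 2))  # 1.04

# synthetic experiment: 72 subjects, 36 critical items + 50 fillers each
design = sa.build_design_exp1(n_subjects=72, seed=1)
records = sa.generate_dataset(design, seed=1)
table, loss = sa.run_pipeline(records)        # exclusion, length correction,
print(round(loss, 4))                         # 0.0069  (< 1% data loss)
fit = sa.fit_adaptation_model(table)          # region aggregation, regression
print(round(fit.coef("sentence_type:ambiguity:item_order"), 2))  # 1.43
```

The final number is the three-way sentence type × ambiguity × item order
interaction at the disambiguating region — the adaptation estimate. Its
positive sign means the (negatively coded) RC garden-path contrast shrinks
as readers accumulate RC evidence; in this run it is significant
(t ≈ 5.0).

The same interfaces are exposed on the command line:

```bash
synadapt simulate-beliefs --experiment exp1 --out out/
synadapt generate-data    --experiment exp2 --seed 1 --out out/
synadapt analyze out/trials_exp2.csv --experiment exp2 --out out/
synadapt recover --n-replicates 100 --seed 1 --out out/
```

## Layout

- `synadapt.belief` — Dirichlet–multinomial belief updating, surprisal,
  trajectory simulation, α₀ calibration
- `synadapt.rt_link` — surprisal → reading-time link and generative
  nuisance parameters
- `synadapt.generate` — experiment designs, synthetic reading-time
  generator, trial CSV dialect
- `synadapt.analysis` — exclusion, length correction, region aggregation,
  factorial/simple-effect/blocked analyses, recovery studies
- `synadapt.config`, `synadapt.cli` — run configuration and the
  `synadapt` command

See `docs/methods.md` for modelling assumptions, parameter conventions and
known limitations.
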