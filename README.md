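# covisim

Dual-system category-learning simulations: how can a procedural
(striatal, reinforcement-learning) memory system learn a categorization
task during the long stretch of early training when an explicit
(rule-based, prefrontal) system controls every response and there is
only one feedback signal?

`covisim` is for computational cognitive scientists and systems
neuroscientists who want to re-run, probe, or extend this question at
desk scale.  It implements the COVIS dual-system architecture with a
hard-coded explicit rule and a 625-unit radial-basis → striatal network
trained by a dopaminergic three-factor rule, five interaction
architectures, the category-structure generators, and a
parameter-space-partitioning (PSP) harness that maps each region of
parameter space to the accuracy decile it produces.

## The model in brief

On each trial with stimulus **x** (grid coordinates, 25×25 space):

* explicit system: h_E = x_d − C_d for the best 1D rule (A iff h_E < 0);
  confidence |h_E|;
* procedural system: I_K = exp(−d(K, x)²/σ_R), S_J = Σ_K w_KJ I_K
  (A iff S_A > S_B); confidence |h_P| = |S_A − S_B|;
* arbitration (soft switching): the explicit system responds iff
  θ_E|h_E| ≥ θ_P|h_P|, with trust θ_E updated each trial by
  Δ_OC(1 − θ_E) on correct explicit suggestions and −Δ_OE θ_E on errors;
* dopamine: D = clip(0.8·RPE + 0.2, 0, 1), RPE = R − P,
  P ← P + α_pr(R − P);
* learning (responded unit's column only):
  Δw_K = α I_K [S_J − θ_NMDA]⁺[D − D_base]⁺(w_max − w_K)
  − β I_K [S_J − θ_NMDA]⁺[D_base − D]⁺ w_K − γ I_K [θ_NMDA − S_J]⁺[S_J − θ_AMPA]⁺ w_K;
* bootstrapping (optional): on explicit-controlled trials, S_J ← S_J + |h_E|
  for the unit matching the explicit response, before feedback.

Architectures: independent feedback + soft switch (2FB-SS), single
feedback + never switch (1FB-HS), single feedback + soft switch
(1FB-SS), and the bootstrapped variants 1FB-HS-B / 1FB-SS-B.  See
`docs/methods.md` for assumptions, parameters, and numerical choices.

## Worked example

Generate the standard information-integration categories (300 stimuli
per category from overlapping bivariate normals whose optimal bound is
the diagonal), then train the bootstrapped never-switching model — the
explicit rule controls every response, yet the procedural network
learns through the injected copy of the rule's choices:

```console
$ covisim gencats --kind ii --n-per-category 300 --seed 7 --out ii.csv
wrote 600 stimuli (II) to ii.csv
$ covisim simulate --stimuli ii.csv --model 1FB-HS-B --epochs 32 --seed 3 --out-dir run1
test accuracy 0.978, procedural control 0.000
```

The procedural system never controlled a single trial (the model never
switches), and its best 1D teacher tops out near 78% — yet its
frozen-weight test accuracy is 97.8%: it also learned *not* to make the
responses the rule got wrong.  Without bootstrapping the same
architecture fails; averaged over the fixed 19-seed bank:

```console
$ covisim batch --stimuli ii.csv --model 1FB-HS --epochs 32 --n-seeds 0 --out m1.json
mean test accuracy 0.533 over 19 runs
```

`run1/` also contains the per-trial log (`trial_log.csv`, with R, P,
RPE, D, θ_E per trial) and the trained 25×25 weight maps
(`weights.csv`); `covisim analyze` averages weight maps across runs and
writes A/B weight-ratio grids, and `covisim psp` / `covisim robustness`
run the partitioning and its fresh-seed robustness stage.  The same
functionality is available as a library (`covisim.simulator.run_batch`,
`covisim.psp.grid_partition`, ...).

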