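# panthoot

Phase-wise information analysis of chimpanzee pant-hoot calls.

The pant hoot — the chimpanzee's long-distance call — consists of four
acoustically distinct phases produced in fixed order: **introduction**
(soft, low-frequency "hoo" units), **build-up** (accelerating low-amplitude
pulses), **climax** (loud, high-frequency screams) and **let-down** (faint
pulses resembling the build-up); a call without a climax is not a pant hoot.
This package implements, as a reusable and tested pipeline, an analysis of
which phases carry acoustic correlates of four caller attributes — identity,
age class, social status (Elo-rank class) and behavioural context (travel vs
feeding) — and of which attributes predict whether the optional build-up and
let-down phases are produced at all.

It is aimed at bioacousticians and quantitative ethologists who want the
method as runnable, seeded code rather than a verbal description.

## The method

1. **Features.** Phase clips are framed (30 ms Hamming windows, 50% overlap)
   and converted to MFCCs through a 32-band triangular mel filterbank
   spanning 1–20050 Hz under the HTK mel scale m = 2595·log10(1 + f/700),
   with log band energies and an orthonormal DCT-II; all 32 coefficients are
   kept and delta coefficients (±2-frame regression slope) are appended,
   giving 64 coefficients per frame.
2. **Classification.** For each attribute × phase × window length
   (50–3250 ms in 50 ms steps), one fixed-length segment per call is drawn
   at a random onset (NaN-padded past the clip end), features are
   range-scaled and mean-normalized on the training data only, and a
   soft-margin RBF SVM is scored on a balanced, stratified 80/20 hold-out.
   (C, γ) come from a 110-pair grid (C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}) tuned
   by 5-fold CV on a disjoint ~10% subset. Scores are means over all
   one-class-versus-rest comparisons; the chance baseline is 50%.
3. **Indices.** Occurrence counts (window lengths scoring ≥ 75…95%),
   prominence (their mean), modality specificity (rows sum to 100% across
   phases), phase specificity (columns sum to 100% across attributes), and
   a five-class window-length profile.
4. **Time course.** The classification re-run at fixed onsets 0–3000 ms
   (100 ms steps) relative to each phase's onset; the five best onsets per
   cell are flagged.
5. **Composition.** Presence of the build-up / let-down modelled by a
   mixed-effects logistic regression (context + age + rank, random
   intercept per caller), fitted by Gauss–Hermite-quadrature maximum
   likelihood.

Because the original field recordings are not deposited, the package
includes a synthetic pant-hoot generator with configurable, phase-localized
attribute signatures and context-dependent phase omission; it defines the
conditions under which every quantitative check here runs. See
`docs/methods.md` for the model details and design choices.

## Worked example

Fit the phase-presence model to a simulated corpus of 400 calls drawn at the
default presence rates (build-up present in 95.58% of travel and 73.17% of
feeding calls):

```python
import panthoot as ph
from panthoot.synth import make_composition_table
from panthoot.composition import fit_presence_model

pop = ph.make_population(10, seed=1)
tab = make_composition_table(pop, 400, seed=7)
print(fit_presence_model(tab, "build-up").summary())
```

```
Phase-presence model: build-up
  calls: 400   callers: 10
  random-intercept sd (caller): 0.000
  log-likelihood: -126.71   converged: True
  term             beta      se       z        P              95% CI
  intercept       3.279   0.792    4.14 3.47e-05   [  1.73,   4.83]
  context        -2.008   0.374   -5.37 8.04e-08   [ -2.74,  -1.27]
  age_years      -0.003   0.030   -0.10    0.923   [ -0.06,   0.06]
  elo_rank       -0.011   0.057   -0.18    0.854   [ -0.12,   0.10]
```

The context coefficient is the log-odds change from travel to feeding: here
−2.01 (true generating contrast logit(0.7317) − logit(0.9558) = −2.07),
i.e. calls produced while feeding are far less likely to contain a build-up;
age and rank, which do not influence omission in the generator, are
correctly near zero. The random-intercept standard deviation is at its
boundary (the generator has no caller-level omission heterogeneity).

The full pipeline is available from the shell:

```sh
panthoot all --seed 1 --outdir run1          # simulate ... composition
panthoot classify --config my.yaml --outdir run1   # re-run one stage
```

Each stage writes CSV/JSON outputs plus a manifest with content hashes;
two runs with the same seed produce byte-identical tables.

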