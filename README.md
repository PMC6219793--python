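# emodyn

Temporal features of emotion episodes and their BOLD correlates.

When people are hit by an emotional event — here, negative social feedback —
the felt intensity of the emotion unfolds over time in characteristic ways.
Two dynamic features dominate: **explosiveness** (how steeply intensity
shoots up at the start of the episode) and **accumulation** (whether
intensity keeps building over the episode instead of returning to baseline).
`emodyn` implements, as a reusable and fully tested pipeline, an analysis
linking these self-reported profile features to brain activity and to a
perspective-taking manipulation (processing the feedback self-immersed, in
the first person, vs self-distanced, as a detached observer), together with
a synthetic-study generator so every stage can be exercised end to end
without scanner data.

## The model

Participants retrospectively draw the intensity of negative affect over each
90 s read-and-think epoch. Each drawn curve is linearly interpolated and
discretised onto 44 equally spaced samples (one per acquired volume at
TR = 2.04 s). The 384 negative-trial profiles (32 participants × 2 runs ×
6 negative trials) are stacked into a nonnegative matrix **X** (384 × 44)
and factorised by two-component nonnegative matrix factorisation,

    X ≈ W H,   W ≥ 0 (trial × 2 scores),  H ≥ 0 (2 × 44 loadings),

fit by multi-restart Lee–Seung multiplicative updates on ‖X − WH‖_F. The
early-peaked component is explosiveness, the monotonically increasing one
accumulation; each trial splits additively into two *subprofiles*
s_k·h_k. The subprofiles, convolved with the canonical double-gamma HRF,
enter a first-level GLM as parametric regressors alongside boxcars for the
instruction, announcement, negative/neutral feedback epochs and drawing
periods (relaxation is the implicit baseline), six motion parameters, and a
200 s discrete-cosine high-pass. Per-subject beta maps go to random-effects
group analyses: voxelwise one-sample t-tests (p < .001 uncorrected, extent
≥ 10 voxels; BH-FDR and sign-flip cluster-level FWER as robustness checks)
and ROI mean-beta t-tests (one-sided, Bonferroni-corrected), including an
anterior/posterior insula split at MNI y = −10. The perspective effect on
the scores themselves is estimated by a multilevel model,

    score_ij = γ0 + b0_i + (γ1 + b1_i)·SD_ij + ε_ij,

with correlated random intercept and slope per participant (REML), the
condition dummy coded 0 = self-immersed, 1 = self-distanced, t = γ̂1/SE with
df = n_obs − n_participants − 1, and standardised slope
β = B·sd(x)/sd(y).

## Worked example

```python
import numpy as np
from emodyn import (SynthConfig, gen_profiles, build_profile_matrix,
                    fit_nnmf, label_components)
from emodyn.behavior import fit_condition_mlm, trial_table_from_scores

cfg = SynthConfig()                       # 32 participants, 2 runs x 10 trials
profiles, truth = gen_profiles(cfg, seed=1)
print(f"{len(profiles)} negative-trial profiles, {cfg.n_samples} samples each")

pm = build_profile_matrix(profiles)       # 384 x 44 nonnegative matrix
model = label_components(fit_nnmf(pm, restarts=50, seed=1))

table = trial_table_from_scores(model.trial_index,
                                model.scores("explosiveness"),
                                model.scores("accumulation"))
for outcome in ("explosiveness", "accumulation"):
    r = fit_condition_mlm(table, outcome)
    print(f"{outcome}: B = {r.B:.2f}, beta = {r.beta_std:.2f}, "
          f"t({r.df}) = {r.t:.2f}, p = {r.p:.2g}, "
          f"95% CI [{r.ci95[0]:.2f}, {r.ci95[1]:.2f}]")
```

prints

```
384 negative-trial profiles, 44 samples each
explosiveness: B = -162.26, beta = -0.29, t(351) = -5.78, p = 1.6e-08, 95% CI [-217.46, -107.07]
accumulation: B = -276.16, beta = -0.27, t(351) = -4.96, p = 1.1e-06, 95% CI [-385.77, -166.55]
```

i.e. on this synthetic study both explosiveness and accumulation scores drop
when the self-distanced perspective is adopted (negative raw slopes B in
drawing-device units per condition step, standardised slopes β ≈ −0.3), with
the degrees of freedom t(351) following from 384 trials, 32 participants and
one level-1 slope.

The same chain is available as a CLI over a shared output directory:

```bash
emodyn simulate --seed 7 --out study/
emodyn decompose --out study/
emodyn fit-first-level --out study/
emodyn group --out study/
emodyn roi --out study/
emodyn behavior --out study/
emodyn report --out study/
```

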