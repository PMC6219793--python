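"""Study-level replication checks run on synthetic data.

Because the neural results cannot be recomputed from the published record
(no raw scanner data), the pipeline is validated by properties that a
correct implementation must exhibit on data with known structure:

* **Null calibration** — on pure-noise group maps, the voxelwise one-sided
  p < .001 exceedance rate must match its nominal level, and the sign-flip
  cluster correction must keep the familywise error rate at or below 5%.
* **Double dissociation** — in a full synthetic study (profiles -> NNMF ->
  subprofile regressors -> first-level OLS -> group ROI tests), a planted
  explosiveness-responsive region must be detected by the explosiveness
  regressor and not by the accumulation regressor, and vice versa —
  the qualitative signature of the ROI replication tables.
* **Multilevel recovery** — the condition model must recover a known fixed
  slope with nominal 95% CI coverage.

These functions are deterministic in their seed and sized to run on a
single CPU in minutes; they back both the test suite and the acceptance
script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior import fit_condition_mlm
from .decomposition import (ACCUMULATION, EXPLOSIVENESS, fit_nnmf,
                            label_components, make_subprofiles)
from .design import assemble_design
from .estimation import (cluster_fwer_signflip, fit_first_level, group_ttest,
                         roi_mean_test, subject_beta_map)
from .io_core import logger
from .profiles import build_profile_matrix
from .synth import SynthConfig, default_planted_rois, gen_mlm_scores, gen_study

__all__ = [
    "voxelwise_null_rate",
    "cluster_fwer_null_rate",
    "DissociationResult",
    "double_dissociation_trial",
    "double_dissociation_count",
    "mlm_recovery",
]


def voxelwise_null_rate(seed: int, n_subjects: int = 32,
                        shape: tuple[int, int, int] = (48, 48, 48),
                        alpha: float = 0.001) -> tuple[float, int]:
    """One-sided p < alpha exceedance rate of a null group t-test.

    Subject maps are i.i.d. standard normal; returns ``(rate, n_voxels)``.
    """
    rng = np.random.default_rng(seed)
    maps = list(rng.normal(size=(n_subjects, *shape)))
    _, _, p_one = group_ttest(maps)
    p = p_one.values[p_one.mask]
    return float((p < alpha).mean()), int(p.size)


def cluster_fwer_null_rate(seed: int, reps: int = 60, n_subjects: int = 12,
                           shape: tuple[int, int, int] = (14, 14, 14),
                           p_unc: float = 0.01, k_extent: int = 3,
                           n_perms: int = 199,
                           alpha: float = 0.05) -> tuple[float, int]:
    """Fraction of null simulations with any FWER-significant cluster.

    A liberal forming threshold and small extent are used so that clusters
    actually occur under the null and the correction is exercised; validity
    of the sign-flip max-cluster method does not depend on these settings.
    """
    rng = np.random.default_rng(seed)
    false_positives = 0
    for rep in range(reps):
        maps = list(rng.normal(size=(n_subjects, *shape)))
        table, _, _ = cluster_fwer_signflip(
            maps, p_unc=p_unc, k_extent=k_extent, n_perms=n_perms,
            seed=int(rng.integers(2**31)))
        if not table.empty and (table["cluster_p_fwer"] < alpha).any():
            false_positives += 1
    return false_positives / reps, reps


@dataclass
class DissociationResult:
    """Group ROI outcome of one synthetic study."""

    seed: int
    p_bonf: dict            # (roi, regressor) -> Bonferroni-corrected p
    t: dict                 # (roi, regressor) -> group T
    matched_detected: bool
    mismatched_silent: bool

    @property
    def dissociated(self) -> bool:
        return self.matched_detected and self.mismatched_silent


def double_dissociation_trial(seed: int, n_participants: int = 10,
                              grid: tuple[int, int, int] = (18, 18, 14),
                              restarts: int = 20,
                              alpha: float = 0.05) -> DissociationResult:
    """Run the full pipeline on one synthetic study and test the planted ROIs.

    Profiles are decomposed afresh (multi-restart NNMF), the resulting
    subprofiles drive per-run first-level GLMs, per-subject beta maps are
    averaged over runs, and each planted ROI's mean beta is tested for each
    regressor with Bonferroni correction (family of 4, as in a 2-ROI x
    2-regressor table).
    """
    cfg = SynthConfig(n_participants=n_participants, grid_shape=grid,
                      planted_rois=default_planted_rois(grid))
    study = gen_study(cfg, seed, with_bold=True)
    pm = build_profile_matrix(study.profiles)
    model = label_components(fit_nnmf(pm, restarts=restarts, seed=seed))
    subs = make_subprofiles(model)
    idx = model.trial_index

    maps = {EXPLOSIVENESS: [], ACCUMULATION: []}
    for pid in study.participant_ids:
        results = []
        for run in study.runs[pid]:
            sel = ((idx["participant_id"] == pid)
                   & (idx["run_id"] == run.run_id)).to_numpy()
            order = np.argsort(idx.loc[sel, "trial_id"].to_numpy())
            run_subs = {label: subs[label][sel][order] for label in subs}
            design = assemble_design(run.events, run_subs, run.motion,
                                     run.bold.n_volumes, cfg.layout.tr_s)
            results.append(fit_first_level(run.bold, design))
        for label in maps:
            maps[label].append(subject_beta_map(results, label))

    p_bonf, t = {}, {}
    for roi in cfg.planted_rois:
        mask = roi.mask(cfg.grid_shape)
        for label in (EXPLOSIVENESS, ACCUMULATION):
            r = roi_mean_test(maps[label], mask, roi.responds_to, label,
                              n_tests_in_family=4)
            p_bonf[(roi.responds_to, label)] = r.p_bonferroni
            t[(roi.responds_to, label)] = r.T
    matched = all(p_bonf[(r, r)] < alpha
                  for r in (EXPLOSIVENESS, ACCUMULATION))
    mismatched = all(p_bonf[(r, o)] >= alpha
                     for r in (EXPLOSIVENESS, ACCUMULATION)
                     for o in (EXPLOSIVENESS, ACCUMULATION) if o != r)
    return DissociationResult(seed=seed, p_bonf=p_bonf, t=t,
                              matched_detected=matched,
                              mismatched_silent=mismatched)


def double_dissociation_count(base_seed: int, n_seeds: int = 20,
                              **kwargs) -> tuple[int, int]:
    """Number of synthetic studies (out of ``n_seeds``) showing the full
    explosiveness/accumulation double dissociation."""
    hits = 0
    for i in range(n_seeds):
        res = double_dissociation_trial(base_seed + i, **kwargs)
        logger.info("dissociation seed %d: matched=%s mismatched_silent=%s",
                    res.seed, res.matched_detected, res.mismatched_silent)
        hits += res.dissociated
    return hits, n_seeds


def mlm_recovery(seed: int, reps: int = 200, gamma1: float = -150.0,
                 n_participants: int = 32, n_neg_per_cond: int = 6) -> dict:
    """Parameter recovery of the multilevel condition model.

    Scores are drawn from the random intercept + slope model with fixed
    condition slope ``gamma1``; each replicate is refit and the slope
    estimate and its Wald 95% CI recorded.  Returns the mean estimate, its
    Monte-Carlo standard error, and the CI coverage.
    """
    rng = np.random.default_rng(seed)
    estimates, covered = [], 0
    for _ in range(reps):
        table = gen_mlm_scores(n_participants=n_participants,
                               n_neg_per_cond=n_neg_per_cond, gamma1=gamma1,
                               seed=int(rng.integers(2**31)))
        res = fit_condition_mlm(table, EXPLOSIVENESS)
        estimates.append(res.B)
        covered += res.ci95[0] <= gamma1 <= res.ci95[1]
    estimates = np.asarray(estimates)
    return {
        "true_slope": gamma1,
        "mean_estimate": float(estimates.mean()),
        "mc_se": float(estimates.std(ddof=1) / np.sqrt(reps)),
        "ci95_coverage": covered / reps,
        "reps": reps,
    }
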