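"""Synthetic study generator: profiles, session timelines, BOLD volumes.

Emulates the statistical structure the analysis assumes so every stage can
be exercised end to end without scanner data:

* drawn intensity profiles are noisy nonnegative combinations of one
  early-peaked loading (explosiveness) and one monotonically increasing
  loading (accumulation), with lognormal per-trial scores whose location is
  multiplied by ``score_delta_distanced`` (< 1: self-distancing lowers both
  features);
* session timelines follow the 2-run x 10-trial layout (6 negative / 4
  neutral per run, never more than two consecutive trials of the same
  valence, self-paced instruction/drawing/relax periods);
* BOLD series contain planted activation clusters responding to the truth
  explosiveness/accumulation regressors (or to negative > neutral), on top
  of low-frequency drift, AR(1) noise, and a motion-coupled component, with
  the true coefficient maps emitted for recovery tests.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from .decomposition import ACCUMULATION, EXPLOSIVENESS
from .design import HRFSpec, boxcar_regressor, parametric_regressors
from .io_core import EVENT_COLUMNS, SessionLayout, VolumeSeries, logger
from .profiles import IntensityProfile

__all__ = [
    "PlantedROI",
    "SynthConfig",
    "default_explosiveness_loading",
    "default_accumulation_loading",
    "gen_valence_order",
    "gen_session_events",
    "gen_profiles",
    "gen_bold",
    "gen_study",
    "gen_mlm_scores",
    "SimulatedRun",
    "SimulatedStudy",
]


def default_explosiveness_loading(n_samples: int = 44,
                                  epoch_s: float = 90.0) -> np.ndarray:
    """Early-peaked unit-norm loading: gamma-shaped, peak in the first third."""
    t = np.linspace(0.0, epoch_s, n_samples)
    h = stats.gamma.pdf(t, a=2.0, scale=6.0)
    return h / np.linalg.norm(h)


def default_accumulation_loading(n_samples: int = 44,
                                 epoch_s: float = 90.0) -> np.ndarray:
    """Smooth monotonically increasing unit-norm loading."""
    t = np.linspace(0.0, epoch_s, n_samples)
    h = (t / epoch_s) ** 1.5
    return h / np.linalg.norm(h)


@dataclass(frozen=True)
class PlantedROI:
    """A spherical activation cluster responding to one truth regressor."""

    center: tuple[int, int, int]
    radius_vox: float
    responds_to: str            # explosiveness | accumulation | negative>neutral
    amplitude: float            # per-volume SNR in noise-SD units

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        lo = np.array(self.center) - self.radius_vox
        hi = np.array(self.center) + self.radius_vox
        if (lo < 0).any() or (hi > np.array(shape) - 1).any():
            raise ValueError(f"planted ROI at {self.center} outside grid {shape}")
        grid = np.indices(shape).reshape(3, -1).T
        d = np.linalg.norm(grid - np.array(self.center), axis=1)
        return (d <= self.radius_vox).reshape(shape)


def default_planted_rois(grid_shape: tuple[int, int, int], radius: float = 2.5,
                         amplitude: float = 0.5) -> tuple[PlantedROI, ...]:
    """One explosiveness- and one accumulation-responsive sphere, placed at
    fixed grid fractions so they scale with the simulated volume."""
    pad = int(np.ceil(radius))

    def at(fracs):
        return tuple(min(max(round(f * n), pad), n - 1 - pad)
                     for f, n in zip(fracs, grid_shape))

    return (
        PlantedROI(at((0.3, 0.3, 0.5)), radius, EXPLOSIVENESS, amplitude),
        PlantedROI(at((0.72, 0.72, 0.5)), radius, ACCUMULATION, amplitude),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generator.

    Score locations are in the device units of the drawing grid (intensity
    axis pixels); defaults give mean profile amplitudes of a few hundred
    units, the scale on which the condition model's raw slopes live.
    ``score_delta_distanced`` multiplies the lognormal location under
    self-distancing (0.7: distancing lowers both features by ~30%).
    """

    n_participants: int = 32
    layout: SessionLayout = field(default_factory=SessionLayout)
    epoch_s: float = 90.0
    score_meanlog: dict = field(default_factory=lambda: {
        EXPLOSIVENESS: float(np.log(500.0)),
        ACCUMULATION: float(np.log(900.0)),
    })
    score_sdlog: float = 0.5
    score_delta_distanced: float = 0.7
    profile_noise_sd: float = 15.0
    randomize_valence_order: bool = True
    instruction_dur_range_s: tuple[float, float] = (8.0, 12.0)
    drawing_dur_range_s: tuple[float, float] = (20.0, 40.0)
    relax_dur_range_s: tuple[float, float] = (8.0, 12.0)
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    planted_rois: tuple[PlantedROI, ...] = default_planted_rois((24, 24, 24))
    noise_sd: float = 1.0
    drift_amplitude: float = 1.0
    ar1_phi: float = 0.3
    motion_sd: float = 0.02
    motion_coupling: float = 0.05
    baseline: float = 100.0
    amplitude_jitter: float = 0.2   # between-subject SD fraction of amplitude

    def __post_init__(self) -> None:
        if not (0 < self.score_delta_distanced <= 1):
            raise ValueError("score_delta_distanced must be in (0, 1]")
        masks = [r.mask(self.grid_shape) for r in self.planted_rois]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if (masks[i] & masks[j]).any():
                    raise ValueError("planted ROIs must be disjoint")

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.epoch_s / self.layout.tr_s))

    def loadings(self) -> dict[str, np.ndarray]:
        return {
            EXPLOSIVENESS: default_explosiveness_loading(self.n_samples, self.epoch_s),
            ACCUMULATION: default_accumulation_loading(self.n_samples, self.epoch_s),
        }


# ---------------------------------------------------------------------------
# Session timelines
# ---------------------------------------------------------------------------

def gen_valence_order(layout: SessionLayout, rng: np.random.Generator,
                      max_tries: int = 10_000) -> tuple[str, ...]:
    """Random trial valence sequence with <= 2 consecutive same-valence trials."""
    base = (["negative"] * layout.n_negative_per_run
            + ["neutral"] * layout.n_neutral_per_run)
    for _ in range(max_tries):
        order = list(rng.permutation(base))
        runs, longest = 1, 1
        for a, b in zip(order, order[1:]):
            runs = runs + 1 if a == b else 1
            longest = max(longest, runs)
        if longest <= 2:
            return tuple(order)
    raise ValueError("could not satisfy the valence sequence constraints")


def gen_session_events(cfg: SynthConfig, rng: np.random.Generator, run_id: int,
                       perspective: str,
                       valence_order: tuple[str, ...] | None = None) -> pd.DataFrame:
    """One run's event table: instruction, then per trial announce / feedback
    (the 90 s read-and-think epoch) / drawing / relax."""
    layout = cfg.layout
    if valence_order is None:
        valence_order = (gen_valence_order(layout, rng)
                         if cfg.randomize_valence_order
                         else layout.valence_order[run_id % layout.n_runs])
    rows = []
    t = 0.0
    dur = rng.uniform(*cfg.instruction_dur_range_s)
    rows.append((run_id, 0, "perspective_instruction", t, dur, perspective, ""))
    t += dur
    for trial, valence in enumerate(valence_order, start=1):
        rows.append((run_id, trial, "announce", t, layout.announce_dur_s,
                     perspective, valence))
        t += layout.announce_dur_s
        rows.append((run_id, trial, f"feedback_{valence}", t, layout.epoch_s,
                     perspective, valence))
        t += layout.epoch_s
        dur = rng.uniform(*cfg.drawing_dur_range_s)
        rows.append((run_id, trial, "drawing", t, dur, perspective, valence))
        t += dur
        dur = rng.uniform(*cfg.relax_dur_range_s)
        rows.append((run_id, trial, "relax", t, dur, perspective, valence))
        t += dur
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def _draw_scores(cfg: SynthConfig, rng: np.random.Generator, perspective: str,
                 size: int) -> dict[str, np.ndarray]:
    delta = cfg.score_delta_distanced if perspective == "self_distanced" else 1.0
    return {
        comp: rng.lognormal(mean=cfg.score_meanlog[comp] + np.log(delta),
                            sigma=cfg.score_sdlog, size=size)
        for comp in (EXPLOSIVENESS, ACCUMULATION)
    }


def gen_profiles(cfg: SynthConfig, seed: int):
    """Drawn profiles for all participants + the ground-truth score table.

    Negative-feedback trials get profiles built as
    ``s_expl * h_expl + s_acc * h_acc`` plus truncated-at-zero Gaussian
    noise; the raw points live on the epoch time axis so resampling at the
    default grid reproduces them.  Returns ``(profiles, truth)`` where
    ``truth`` holds the generating scores per trial.
    """
    rng = np.random.default_rng(seed)
    loadings = cfg.loadings()
    profiles: list[IntensityProfile] = []
    truth_rows = []
    t_axis = np.linspace(0.0, cfg.epoch_s, cfg.n_samples)
    for p in range(cfg.n_participants):
        pid = f"sub{p + 1:02d}"
        first = "self_immersed" if p % 2 == 0 else "self_distanced"
        order = "SI_first" if first == "self_immersed" else "SD_first"
        layout = cfg.layout.with_perspective_order(first)
        for run_id, perspective in enumerate(layout.perspective_per_run):
            valence_order = (gen_valence_order(layout, rng)
                             if cfg.randomize_valence_order
                             else layout.valence_order[run_id])
            neg_trials = [i + 1 for i, v in enumerate(valence_order)
                          if v == "negative"]
            scores = _draw_scores(cfg, rng, perspective, len(neg_trials))
            for j, trial in enumerate(neg_trials):
                clean = (scores[EXPLOSIVENESS][j] * loadings[EXPLOSIVENESS]
                         + scores[ACCUMULATION][j] * loadings[ACCUMULATION])
                noisy = np.clip(
                    clean + rng.normal(0.0, cfg.profile_noise_sd, cfg.n_samples),
                    0.0, None)
                profiles.append(IntensityProfile(
                    participant_id=pid, run_id=run_id, trial_id=trial,
                    perspective=perspective, valence="negative",
                    raw_points=np.column_stack([t_axis, noisy]),
                    sampled=noisy,
                ))
                truth_rows.append({
                    "participant_id": pid, "run_id": run_id, "trial_id": trial,
                    "perspective": perspective, "order": order,
                    EXPLOSIVENESS: scores[EXPLOSIVENESS][j],
                    ACCUMULATION: scores[ACCUMULATION][j],
                })
    truth = pd.DataFrame(truth_rows)
    logger.info("gen_profiles: %d negative-trial profiles, %d participants",
                len(profiles), cfg.n_participants)
    return profiles, truth


# ---------------------------------------------------------------------------
# BOLD volumes
# ---------------------------------------------------------------------------

def _brain_sphere(shape: tuple[int, int, int]) -> np.ndarray:
    center = (np.array(shape) - 1) / 2
    grid = np.indices(shape).reshape(3, -1).T
    radius = min(shape) / 2 - 0.5
    return (np.linalg.norm(grid - center, axis=1) <= radius).reshape(shape)


def _truth_regressor(roi: PlantedROI, events: pd.DataFrame,
                     subprofiles: dict[str, np.ndarray], n_volumes: int,
                     tr_s: float, spec: HRFSpec) -> np.ndarray:
    if roi.responds_to in (EXPLOSIVENESS, ACCUMULATION):
        expl, acc = parametric_regressors(
            subprofiles[EXPLOSIVENESS], subprofiles[ACCUMULATION],
            events, n_volumes, tr_s, spec)
        return expl if roi.responds_to == EXPLOSIVENESS else acc
    if roi.responds_to == "negative>neutral":
        neg = boxcar_regressor(events, "feedback_negative", n_volumes, tr_s, spec)
        neu = boxcar_regressor(events, "feedback_neutral", n_volumes, tr_s, spec)
        return neg - neu
    raise ValueError(f"unknown planted response {roi.responds_to!r}")


def gen_bold(cfg: SynthConfig, events: pd.DataFrame,
             subprofiles: dict[str, np.ndarray], seed: int,
             amplitude_scale: float = 1.0,
             hrf_spec: HRFSpec = HRFSpec()):
    """Simulate one run's 4-D BOLD series.

    Voxel time series inside each planted ROI gain
    ``amplitude * noise_sd * x / sd(x)`` where ``x`` is the HRF-convolved
    truth regressor — so ``amplitude`` is the per-volume SNR — on top of a
    baseline, slow cosine drift, AR(1) Gaussian noise, and a small
    motion-coupled component.  Returns ``(VolumeSeries, motion (n x 6),
    truth_betas: {regressor: 3-D map of true coefficients})``.
    """
    rng = np.random.default_rng(seed)
    tr = cfg.layout.tr_s
    run_end = (events["onset_s"] + events["duration_s"]).max()
    n_volumes = int(np.ceil(run_end / tr)) + 2
    shape = cfg.grid_shape
    brain = _brain_sphere(shape)
    n_vox = int(brain.sum())

    # AR(1) noise with stationary SD = noise_sd
    innov_sd = cfg.noise_sd * np.sqrt(1 - cfg.ar1_phi ** 2)
    noise = rng.normal(0.0, innov_sd, size=(n_vox, n_volumes))
    noise = sp_signal.lfilter([1.0], [1.0, -cfg.ar1_phi], noise, axis=1)

    # slow cosine drift, per-voxel random period/phase/amplitude
    t = np.arange(n_volumes) * tr
    periods = rng.uniform(150.0, 400.0, n_vox)
    phases = rng.uniform(0, 2 * np.pi, n_vox)
    amps = rng.uniform(0, cfg.drift_amplitude, n_vox) * cfg.noise_sd
    drift = amps[:, None] * np.cos(2 * np.pi * t[None, :] / periods[:, None]
                                   + phases[:, None])

    # slowly wandering motion parameters + coupled artefact
    motion = np.cumsum(rng.normal(0.0, cfg.motion_sd, size=(n_volumes, 6)), axis=0)
    weights = rng.normal(0.0, 1.0, size=(n_vox, 6))
    motion_term = cfg.motion_coupling * cfg.noise_sd * (weights @ motion.T)

    series = cfg.baseline + noise + drift + motion_term

    truth_betas: dict[str, np.ndarray] = {}
    flat_index = np.full(shape, -1)
    flat_index[brain] = np.arange(n_vox)
    for roi in cfg.planted_rois:
        x = _truth_regressor(roi, events, subprofiles, n_volumes, tr, hrf_spec)
        sd_x = x.std()
        if sd_x == 0:
            raise ValueError(f"degenerate truth regressor for {roi.responds_to}")
        coef = amplitude_scale * roi.amplitude * cfg.noise_sd / sd_x
        roi_vox = flat_index[roi.mask(shape) & brain]
        series[roi_vox] += coef * x[None, :]
        beta_map = truth_betas.setdefault(roi.responds_to, np.zeros(shape))
        beta_map[roi.mask(shape) & brain] = coef

    data = np.zeros(shape + (n_volumes,))
    data[brain] = series
    affine = np.diag([cfg.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -(np.array(shape) - 1) / 2 * cfg.voxel_size_mm
    vs = VolumeSeries(data=data, affine=affine, tr_s=tr, brain_mask=brain,
                      voxel_size_mm=(cfg.voxel_size_mm,) * 3)
    return vs, motion, truth_betas


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRun:
    run_id: int
    perspective: str
    events: pd.DataFrame
    subprofiles_truth: dict[str, np.ndarray]
    bold: VolumeSeries | None = None
    motion: np.ndarray | None = None
    truth_betas: dict[str, np.ndarray] | None = None


@dataclass
class SimulatedStudy:
    config: SynthConfig
    seed: int
    profiles: list
    truth_scores: pd.DataFrame
    runs: dict[str, list[SimulatedRun]]        # participant_id -> runs

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.runs)


def gen_study(cfg: SynthConfig, seed: int, with_bold: bool = True) -> SimulatedStudy:
    """Generate a full synthetic study: profiles, events, (optionally) BOLD.

    Each participant's event tables, truth subprofiles and simulated runs
    are derived from one root seed, so the study is a pure function of
    (config, seed).
    """
    profiles, truth = gen_profiles(cfg, seed)
    loadings = cfg.loadings()
    root = np.random.default_rng(seed + 1_000_003)
    runs: dict[str, list[SimulatedRun]] = {}
    for p in range(cfg.n_participants):
        pid = f"sub{p + 1:02d}"
        first = "self_immersed" if p % 2 == 0 else "self_distanced"
        layout = cfg.layout.with_perspective_order(first)
        amp_scale = max(0.1, 1.0 + root.normal(0.0, cfg.amplitude_jitter))
        run_list = []
        for run_id, perspective in enumerate(layout.perspective_per_run):
            sub = truth[(truth["participant_id"] == pid)
                        & (truth["run_id"] == run_id)].sort_values("trial_id")
            valence_order = _order_from_truth(sub, layout)
            events = gen_session_events(
                cfg, root, run_id, perspective, valence_order=valence_order)
            subprofiles = {
                comp: np.outer(sub[comp].to_numpy(), loadings[comp])
                for comp in (EXPLOSIVENESS, ACCUMULATION)
            }
            run = SimulatedRun(run_id=run_id, perspective=perspective,
                               events=events, subprofiles_truth=subprofiles)
            if with_bold:
                run.bold, run.motion, run.truth_betas = gen_bold(
                    cfg, events, subprofiles, seed=int(root.integers(2**31)),
                    amplitude_scale=amp_scale)
            run_list.append(run)
        runs[pid] = run_list
    return SimulatedStudy(config=cfg, seed=seed, profiles=profiles,
                          truth_scores=truth, runs=runs)


def _order_from_truth(sub: pd.DataFrame, layout: SessionLayout) -> tuple[str, ...]:
    neg = set(sub["trial_id"])
    return tuple("negative" if i + 1 in neg else "neutral"
                 for i in range(layout.trials_per_run))


# ---------------------------------------------------------------------------
# Direct mixed-model score generator (parameter-recovery oracle)
# ---------------------------------------------------------------------------

def gen_mlm_scores(n_participants: int = 32, n_neg_per_cond: int = 6,
                   gamma0: float = 600.0, gamma1: float = -150.0,
                   sd_intercept: float = 150.0, sd_slope: float = 80.0,
                   re_corr: float = 0.2, sd_resid: float = 250.0,
                   seed: int = 0, outcome: str = EXPLOSIVENESS) -> pd.DataFrame:
    """Trial scores drawn directly from the random intercept + slope model.

    ``score = gamma0 + b0_i + (gamma1 + b1_i) * dummy + eps`` with
    participant effects (b0, b1) bivariate normal.  Used as the independent
    oracle for multilevel parameter recovery; the known fixed slope is
    ``gamma1``.
    """
    rng = np.random.default_rng(seed)
    cov = np.array([
        [sd_intercept ** 2, re_corr * sd_intercept * sd_slope],
        [re_corr * sd_intercept * sd_slope, sd_slope ** 2],
    ])
    rows = []
    other = ACCUMULATION if outcome == EXPLOSIVENESS else EXPLOSIVENESS
    for p in range(n_participants):
        pid = f"sub{p + 1:02d}"
        b0, b1 = rng.multivariate_normal([0.0, 0.0], cov)
        order = "SI_first" if p % 2 == 0 else "SD_first"
        trial = 0
        for dummy in (0, 1):
            for _ in range(n_neg_per_cond):
                trial += 1
                y = gamma0 + b0 + (gamma1 + b1) * dummy + rng.normal(0, sd_resid)
                rows.append({
                    "participant_id": pid, "trial": trial,
                    "condition_dummy": dummy, "order": order,
                    outcome: y, other: 0.0,
                })
    return pd.DataFrame(rows)
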