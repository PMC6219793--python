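"""File formats, session layout, run configuration and logging.

The pipeline exchanges data in plain, inspectable formats: NIfTI-1 for 4-D
BOLD series, statistic maps and ROI masks; CSV for drawn intensity profiles,
event timing tables, motion parameters and component scores; YAML for the run
configuration.  Everything downstream (profile resampling, NNMF, GLM, group
statistics) consumes the in-memory containers defined here.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("emodyn")

__all__ = [
    "SessionLayout",
    "VolumeSeries",
    "StatMap",
    "EVENT_CLASSES",
    "EVENT_COLUMNS",
    "validate_events",
    "read_events_csv",
    "write_events_csv",
    "read_motion_csv",
    "read_bold",
    "write_bold",
    "read_mask",
    "write_mask",
    "write_stat_map",
    "read_stat_map",
    "DEFAULTS",
    "load_config",
    "config_hash",
    "file_checksum",
    "setup_logging",
]


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger for console output."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance logs."""
    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def file_checksum(path: str | Path) -> str:
    """SHA-256 checksum (first 12 hex digits) of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


# ---------------------------------------------------------------------------
# Session layout
# ---------------------------------------------------------------------------

#: Default per-run valence sequence: 6 negative + 4 neutral feedback trials
#: with never more than two consecutive trials of the same valence.
_DEFAULT_VALENCE_ORDER = (
    "negative", "negative", "neutral", "negative", "negative",
    "neutral", "negative", "neutral", "negative", "neutral",
)


@dataclass(frozen=True)
class SessionLayout:
    """Timing skeleton of one scanning session.

    A session consists of ``n_runs`` runs of ``trials_per_run`` feedback
    trials each.  Every trial shows a 5 s announcement screen, then the
    feedback for ``feedback_dur_s`` (reading) followed by a fixation cross
    for ``fixation_dur_s`` (thinking); the two together form the 90 s
    read-and-think epoch that is modeled as one event.  The perspective
    manipulation (self-immersed vs self-distanced) is applied per run.
    """

    n_runs: int = 2
    trials_per_run: int = 10
    n_negative_per_run: int = 6
    n_neutral_per_run: int = 4
    announce_dur_s: float = 5.0
    feedback_dur_s: float = 30.0
    fixation_dur_s: float = 60.0
    tr_s: float = 2.04
    valence_order: tuple[tuple[str, ...], ...] = (
        _DEFAULT_VALENCE_ORDER, _DEFAULT_VALENCE_ORDER,
    )
    perspective_per_run: tuple[str, ...] = ("self_immersed", "self_distanced")

    def __post_init__(self) -> None:
        if self.n_negative_per_run + self.n_neutral_per_run != self.trials_per_run:
            raise ValueError("negative + neutral trial counts must equal trials_per_run")
        for name in ("announce_dur_s", "feedback_dur_s", "fixation_dur_s", "tr_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.valence_order) != self.n_runs:
            raise ValueError("valence_order must list one sequence per run")
        if len(self.perspective_per_run) != self.n_runs:
            raise ValueError("perspective_per_run must list one perspective per run")
        for order in self.valence_order:
            if len(order) != self.trials_per_run:
                raise ValueError("each valence sequence must have trials_per_run entries")
            if order.count("negative") != self.n_negative_per_run:
                raise ValueError("valence sequence has wrong negative-trial count")
            if _max_run_length(order) > 2:
                raise ValueError(
                    "more than two consecutive trials of the same valence"
                )
        bad = set(self.perspective_per_run) - {"self_immersed", "self_distanced"}
        if bad:
            raise ValueError(f"unknown perspective labels: {sorted(bad)}")

    @property
    def epoch_s(self) -> float:
        """Duration of the modeled read-and-think epoch (feedback + fixation)."""
        return self.feedback_dur_s + self.fixation_dur_s

    @property
    def n_samples(self) -> int:
        """Number of volume-aligned profile samples: floor(epoch / TR)."""
        return int(np.floor(self.epoch_s / self.tr_s))

    def with_perspective_order(self, first: str) -> "SessionLayout":
        """Return a copy with the given perspective in run 1 (counterbalancing)."""
        other = ("self_distanced" if first == "self_immersed" else "self_immersed")
        order = tuple((first, other)[i % 2] for i in range(self.n_runs))
        return replace(self, perspective_per_run=order)


def _max_run_length(seq) -> int:
    longest = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    return longest


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

EVENT_CLASSES = (
    "perspective_instruction",
    "announce",
    "feedback_negative",
    "feedback_neutral",
    "drawing",
    "relax",
)

EVENT_COLUMNS = [
    "run_id", "trial_id", "event_class", "onset_s", "duration_s",
    "perspective", "valence",
]


def validate_events(events: pd.DataFrame, layout: SessionLayout | None = None) -> pd.DataFrame:
    """Check an event table: columns, classes, ordering, non-overlap.

    Feedback events must span the full read-and-think epoch
    (``feedback_dur_s + fixation_dur_s``) when a layout is given.
    """
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    bad = set(events["event_class"]) - set(EVENT_CLASSES)
    if bad:
        raise ValueError(f"unknown event classes: {sorted(bad)}")
    if (events["duration_s"] < 0).any():
        raise ValueError("negative event duration")
    for run_id, run in events.groupby("run_id"):
        onsets = run["onset_s"].to_numpy(float)
        ends = onsets + run["duration_s"].to_numpy(float)
        order = np.argsort(onsets, kind="stable")
        if not np.all(np.diff(onsets[order]) > 0):
            raise ValueError(f"run {run_id}: onsets not strictly increasing")
        if np.any(onsets[order][1:] < ends[order][:-1] - 1e-9):
            raise ValueError(f"run {run_id}: overlapping events")
    if layout is not None:
        fb = events[events["event_class"].isin(["feedback_negative", "feedback_neutral"])]
        if not np.allclose(fb["duration_s"], layout.epoch_s):
            raise ValueError(
                "feedback events must span the full read-and-think epoch "
                f"({layout.epoch_s:g} s)"
            )
    return events


def read_events_csv(path: str | Path, layout: SessionLayout | None = None) -> pd.DataFrame:
    return validate_events(pd.read_csv(path), layout)


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events)
    events.to_csv(path, index=False)


def read_motion_csv(path: str | Path, n_volumes: int | None = None) -> np.ndarray:
    """Read a 6-column motion-parameter table (3 translations mm, 3 rotations rad)."""
    table = pd.read_csv(path)
    if table.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got {table.shape[1]}")
    if n_volumes is not None and len(table) != n_volumes:
        raise ValueError(
            f"motion table has {len(table)} rows, expected {n_volumes} volumes"
        )
    return table.to_numpy(float)


# ---------------------------------------------------------------------------
# Volumes and statistic maps
# ---------------------------------------------------------------------------

@dataclass
class VolumeSeries:
    """A 4-D BOLD series with its grid metadata and brain mask."""

    data: np.ndarray              # (x, y, z, t)
    affine: np.ndarray            # 4x4 grid-to-world map
    tr_s: float
    brain_mask: np.ndarray        # 3-D boolean
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("non-4-D image")
        if self.tr_s <= 0:
            raise ValueError("non-positive TR")
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal spatial shape")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class StatMap:
    """A 3-D per-voxel statistic volume with its grid metadata.

    ``kind`` is one of beta/t/p/q; out-of-mask voxels are NaN.
    """

    values: np.ndarray
    kind: str
    df: float
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.kind in ("p", "q"):
            inm = self.values[self.mask]
            inm = inm[np.isfinite(inm)]
            if inm.size and (inm.min() < -1e-12 or inm.max() > 1 + 1e-12):
                raise ValueError(f"{self.kind}-values outside [0, 1]")


def default_brain_mask(data: np.ndarray, mask_frac: float = 0.2) -> np.ndarray:
    """Voxels whose temporal mean exceeds ``mask_frac`` of the global maximum mean."""
    mean = data.mean(axis=3)
    return mean > mask_frac * mean.max()


def read_bold(path: str | Path, tr_override: float | None = None,
              mask_frac: float = 0.2) -> VolumeSeries:
    """Load a 4-D NIfTI BOLD series.

    TR is read from the header (zooms) unless ``tr_override`` is given;
    the brain mask defaults to a temporal-mean intensity threshold.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 4:
        raise ValueError("non-4-D image")
    tr = tr_override if tr_override is not None else float(img.header.get_zooms()[3])
    if tr <= 0:
        raise ValueError("non-positive TR")
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = default_brain_mask(data, mask_frac)
    logger.info("read_bold %s: shape=%s TR=%.4g checksum=%s",
                path.name, data.shape, tr, file_checksum(path))
    return VolumeSeries(data=data, affine=np.asarray(img.affine, float), tr_s=tr,
                        brain_mask=mask, voxel_size_mm=vox)


def write_bold(vs: VolumeSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(vs.data.astype(np.float64), vs.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = vs.tr_s
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a binary ROI/brain mask NIfTI; returns (bool array, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    return data > 0.5, np.asarray(img.affine, float)


def write_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def write_stat_map(stat_map: StatMap, path: str | Path,
                   reference_affine: np.ndarray | None = None) -> None:
    """Write a statistic map as NIfTI; out-of-mask voxels are stored as 0."""
    if reference_affine is not None and not np.allclose(
            stat_map.affine, reference_affine, atol=1e-6):
        raise ValueError("stat map affine does not match the reference grid")
    vol = np.where(stat_map.mask, stat_map.values, 0.0)
    vol = np.nan_to_num(vol, nan=0.0)
    img = nib.Nifti1Image(vol.astype(np.float64), stat_map.affine)
    img.header["descrip"] = f"emodyn {stat_map.kind} df={stat_map.df:g}".encode()[:80]
    nib.save(img, str(path))


def read_stat_map(path: str | Path, kind: str = "t", df: float = np.nan) -> StatMap:
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=np.float64)
    mask = values != 0
    values = np.where(mask, values, np.nan)
    return StatMap(values=values, kind=kind, df=df,
                   affine=np.asarray(img.affine, float), mask=mask)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: Defaults for the full pipeline.  Analysis constants reflect the study
#: design: 44 volume-aligned profile samples, 200 s high-pass cutoff,
#: voxelwise p<.001 uncorrected with a 10-voxel extent threshold, and the
#: anterior/posterior insula split at MNI y = -10 mm.
DEFAULTS: dict = {
    "n_participants": 32,
    "tr_s": 2.04,
    "n_samples": 44,
    "epoch_s": 90.0,
    "hp_cutoff_s": 200.0,
    "p_unc": 0.001,
    "k_extent": 10,
    "insula_split_y": -10.0,
    "connectivity": 18,
    "nnmf_restarts": 50,
    "nnmf_max_iter": 2000,
    "nnmf_tol": 1e-9,
    "mask_frac": 0.2,
    "grid_shape": [24, 24, 24],
    "seed": 0,
}

_RANGE_CHECKS = {
    "n_participants": lambda v: v >= 1,
    "tr_s": lambda v: v > 0,
    "n_samples": lambda v: v >= 2,
    "epoch_s": lambda v: v > 0,
    "hp_cutoff_s": lambda v: v > 0,
    "p_unc": lambda v: 0 < v < 1,
    "k_extent": lambda v: v >= 1,
    "insula_split_y": lambda v: np.isfinite(v),
    "connectivity": lambda v: v in (6, 18, 26),
    "nnmf_restarts": lambda v: v >= 1,
    "nnmf_max_iter": lambda v: v >= 1,
    "nnmf_tol": lambda v: v > 0,
    "mask_frac": lambda v: 0 <= v < 1,
    "grid_shape": lambda v: (isinstance(v, (list, tuple)) and len(v) == 3
                             and all(int(s) >= 12 for s in v)),
    "seed": lambda v: 0 <= v < 2**31,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML run configuration, filling defaults and validating strictly.

    Unknown keys and out-of-range values are rejected.  An empty or missing
    file yields the full default set.
    """
    cfg = dict(DEFAULTS)
    user: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config must be a mapping")
        user.update(loaded)
    if overrides:
        user.update(overrides)
    unknown = set(user) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    for key, ok in _RANGE_CHECKS.items():
        if not ok(cfg[key]):
            raise ValueError(f"config value out of range: {key}={cfg[key]!r}")
    logger.info("config loaded: hash=%s", config_hash(cfg))
    return cfg
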