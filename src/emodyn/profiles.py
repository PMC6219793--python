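"""Drawn emotion-intensity profiles: cleaning, resampling, stacking.

After each feedback trial participants retrospectively drew a continuous
curve of felt negative-affect intensity over the 90 s read-and-think epoch
(x = time in device units, y = intensity on a 7-interval axis in device
units).  Each drawn curve is linearly interpolated and discretised onto a
grid of ``n_samples`` equally spaced points — by default floor(90 / 2.04)
= 44, one per acquired volume of the epoch.  Negative-feedback trials are
then stacked into the nonnegative matrix that feeds the NNMF decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import logger

__all__ = [
    "IntensityProfile",
    "ProfileMatrix",
    "default_n_samples",
    "clean_raw_curve",
    "resample_profile",
    "build_profile_matrix",
    "read_profiles_csv",
    "write_profiles_csv",
    "PROFILE_COLUMNS",
]

#: Canonical long-format CSV schema: one row per drawn point.
PROFILE_COLUMNS = [
    "participant_id", "run_id", "trial_id", "perspective", "valence", "x", "y",
]


def default_n_samples(epoch_s: float = 90.0, tr_s: float = 2.04) -> int:
    """Number of volume-aligned samples in a read-and-think epoch: floor(epoch/TR)."""
    return int(np.floor(epoch_s / tr_s))


@dataclass
class IntensityProfile:
    """One trial's drawn intensity curve and its resampled vector."""

    participant_id: str
    run_id: int
    trial_id: int
    perspective: str            # self_immersed | self_distanced
    valence: str                # negative | neutral
    raw_points: np.ndarray      # (n, 2): x device units, y device units
    sampled: np.ndarray | None = None

    @property
    def key(self) -> tuple:
        return (self.participant_id, self.run_id, self.trial_id)


@dataclass
class ProfileMatrix:
    """Stacked resampled profiles (rows = trials, columns = time samples)."""

    X: np.ndarray                 # (n_trials, n_samples), nonnegative
    trial_index: pd.DataFrame     # participant_id, run_id, trial_id, perspective
    time_axis: np.ndarray         # (n_samples,) seconds within the epoch

    def __post_init__(self) -> None:
        if (self.X < 0).any():
            raise ValueError("profile matrix must be nonnegative")
        if len(self.trial_index) != self.X.shape[0]:
            raise ValueError("trial index length must match row count")


def clean_raw_curve(points) -> np.ndarray:
    """Make a drawn trace a function of x: dedupe, sort, clip below zero.

    Trackball traces may backtrack; at each repeated x the *last* drawn y is
    kept (the final stroke reflects the intended value).  Points are then
    sorted by x and y is clipped at 0 from below.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y)")
    # keep the last occurrence of every x, preserving drawing order
    seen: dict[float, float] = {}
    for x, y in pts:
        seen[float(x)] = float(y)
    if len(seen) < 2:
        raise ValueError("need at least 2 distinct x values")
    xs = np.array(sorted(seen))
    ys = np.array([seen[x] for x in xs])
    return np.column_stack([xs, np.clip(ys, 0.0, None)])


def resample_profile(points: np.ndarray, n_samples: int,
                     epoch_s: float = 90.0) -> np.ndarray:
    """Discretise a cleaned curve onto ``n_samples`` equally spaced points.

    The piecewise-linear interpolant of the cleaned points is evaluated at
    ``n_samples`` equally spaced abscissae spanning the drawn x-range; the
    drawn range is mapped affinely onto ``[0, epoch_s]``, so the returned
    vector lives on ``np.linspace(0, epoch_s, n_samples)``.  Values outside
    the drawn range are held at the boundary value.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty curve")
    x, y = pts[:, 0], pts[:, 1]
    grid = np.linspace(x[0], x[-1], n_samples)
    sampled = np.interp(grid, x, y)   # np.interp holds boundary values
    return np.clip(sampled, 0.0, None)


def build_profile_matrix(profiles, valence_filter: str = "negative",
                         epoch_s: float = 90.0) -> ProfileMatrix:
    """Stack resampled profiles of one valence into the NNMF input matrix.

    Rows are ordered by (participant, run, trial).  All profiles must have
    been resampled with the same number of samples; duplicate trial keys and
    an empty post-filter set are errors.
    """
    kept = [p for p in profiles if p.valence == valence_filter]
    if not kept:
        raise ValueError("no rows after filter")
    lengths = {len(p.sampled) for p in kept if p.sampled is not None}
    if any(p.sampled is None for p in kept):
        raise ValueError("all profiles must be resampled first")
    if len(lengths) != 1:
        raise ValueError(f"mixed n_samples: {sorted(lengths)}")
    keys = [p.key for p in kept]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (participant, run, trial) keys")
    kept.sort(key=lambda p: p.key)
    n = lengths.pop()
    X = np.vstack([p.sampled for p in kept])
    index = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in kept],
            "run_id": [p.run_id for p in kept],
            "trial_id": [p.trial_id for p in kept],
            "perspective": [p.perspective for p in kept],
        }
    )
    logger.info("profile matrix: %d x %d (%s trials)", *X.shape, valence_filter)
    return ProfileMatrix(X=X, trial_index=index,
                         time_axis=np.linspace(0.0, epoch_s, n))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_profiles_csv(path: str | Path, column_map: dict[str, str] | None = None,
                      clean: bool = True) -> list[IntensityProfile]:
    """Read drawn profiles from a long-format CSV (one row per point).

    ``column_map`` maps the canonical column names to the names used in the
    file, accommodating exports whose headers differ from the canonical
    schema.
    """
    table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns={v: k for k, v in column_map.items()})
    missing = set(PROFILE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    out: list[IntensityProfile] = []
    group_cols = ["participant_id", "run_id", "trial_id"]
    for key, grp in table.groupby(group_cols, sort=True):
        pts = grp[["x", "y"]].to_numpy(float)
        if clean:
            pts = clean_raw_curve(pts)
        out.append(IntensityProfile(
            participant_id=str(key[0]), run_id=int(key[1]), trial_id=int(key[2]),
            perspective=str(grp["perspective"].iloc[0]),
            valence=str(grp["valence"].iloc[0]),
            raw_points=pts,
        ))
    return out


def write_profiles_csv(profiles, path: str | Path) -> None:
    rows = []
    for p in profiles:
        for x, y in p.raw_points:
            rows.append((p.participant_id, p.run_id, p.trial_id,
                         p.perspective, p.valence, x, y))
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)
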