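"""Two-component NNMF of intensity profiles and subprofile reconstruction.

The stacked negative-trial profile matrix X (trials x time samples, all
entries >= 0) is factorised as X ~ W H with W >= 0 (per-trial component
scores) and H >= 0 (component loadings over time), k = 2.  The early-peaked
component captures *explosiveness* (a steep start followed by decay), the
monotonically increasing one captures *accumulation* (intensity that keeps
building instead of returning to baseline).  Each trial's profile decomposes
additively into two subprofiles, score x loading, which later serve as
parametric BOLD regressors.

The factorisation uses Lee-Seung multiplicative updates for the Frobenius
objective ||X - WH||_F, restarted from multiple random nonnegative
initialisations because the problem is non-convex; the best restart is kept.
Loadings are normalised to unit Euclidean norm with the scale absorbed into
the scores, so scores are comparable across components (all replication
statistics downstream are invariant to this scale convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import logger
from .profiles import ProfileMatrix

__all__ = [
    "ComponentModel",
    "fit_nnmf",
    "label_components",
    "reconstruct_percentile_profiles",
    "make_subprofiles",
    "extract_scores_from_subprofiles",
    "write_scores_csv",
    "write_loadings_csv",
    "write_subprofiles_csv",
    "read_subprofiles_csv",
]

_EPS = 1e-12

EXPLOSIVENESS = "explosiveness"
ACCUMULATION = "accumulation"


@dataclass
class ComponentModel:
    """A fitted nonnegative factorisation X ~ W H.

    ``labels`` maps component row index in H to its interpretation
    (explosiveness / accumulation); it is empty until
    :func:`label_components` is applied.
    """

    W: np.ndarray                        # (n_trials, k) scores
    H: np.ndarray                        # (k, n_samples) unit-norm loadings
    objective_trace: np.ndarray          # per-iteration ||X - WH||_F of best restart
    restarts_used: int
    seed: int
    labels: dict[int, str] = field(default_factory=dict)
    trial_index: pd.DataFrame | None = None
    time_axis: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.H.shape[0]

    def _index_of(self, label: str) -> int:
        for idx, lab in self.labels.items():
            if lab == label:
                return idx
        raise KeyError(f"model has no component labeled {label!r} (labeled? {bool(self.labels)})")

    def scores(self, label: str) -> np.ndarray:
        """Per-trial scores of the named component."""
        return self.W[:, self._index_of(label)]

    def loading(self, label: str) -> np.ndarray:
        """Unit-norm temporal loading of the named component."""
        return self.H[self._index_of(label)]

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


def _mu_fit(X: np.ndarray, k: int, max_iter: int, tol: float,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One multiplicative-update run from a random nonnegative start."""
    n, m = X.shape
    scale = np.sqrt(X.mean() / max(k, 1)) if X.any() else 1.0
    W = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, m)) * scale
    norm_X = np.linalg.norm(X)
    trace = [float(np.linalg.norm(X - W @ H))]
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = float(np.linalg.norm(X - W @ H))
        prev = trace[-1]
        trace.append(obj)
        if prev - obj < tol * max(prev, norm_X * 1e-15, _EPS):
            break
    return W, H, np.asarray(trace)


def fit_nnmf(X: ProfileMatrix | np.ndarray, k: int = 2, restarts: int = 50,
             max_iter: int = 2000, tol: float = 1e-9,
             seed: int = 0) -> ComponentModel:
    """Fit a k-component NNMF by multi-restart multiplicative updates.

    Parameters mirror the decomposition defaults: 50 random restarts,
    up to 2000 iterations each, stopping when the relative decrease of
    ||X - WH||_F falls below ``tol``.  The restart with the lowest final
    objective is kept; with the same seed the result is bit-identical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    trial_index = time_axis = None
    if isinstance(X, ProfileMatrix):
        trial_index, time_axis = X.trial_index, X.time_axis
        X = X.X
    X = np.asarray(X, dtype=np.float64)
    if (X < 0).any():
        raise ValueError("X must be nonnegative")
    zero_rows = int((~X.any(axis=1)).sum())
    if zero_rows:
        logger.warning("fit_nnmf: %d all-zero profile rows", zero_rows)

    root = np.random.default_rng(seed)
    best = None
    for r in range(restarts):
        W, H, trace = _mu_fit(X, k, max_iter, tol, np.random.default_rng(root.integers(2**31)))
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    W, H, trace = best

    # unit-norm loading rows, scale absorbed into the scores
    norms = np.linalg.norm(H, axis=1)
    for i, nrm in enumerate(norms):
        if nrm <= _EPS:                      # degenerate (e.g. X = 0)
            H[i] = 1.0 / np.sqrt(H.shape[1])
            W[:, i] = 0.0
        else:
            H[i] /= nrm
            W[:, i] *= nrm
    logger.info("fit_nnmf: k=%d restarts=%d final ||X-WH||_F=%.6g (%d iters)",
                k, restarts, trace[-1], len(trace) - 1)
    return ComponentModel(W=W, H=H, objective_trace=trace, restarts_used=restarts,
                          seed=seed, trial_index=trial_index, time_axis=time_axis)


def label_components(model: ComponentModel) -> ComponentModel:
    """Identify the explosiveness and accumulation components of a k=2 fit.

    NNMF component order is arbitrary, so identity is assigned by temporal
    shape: the component whose loading-weighted mean time (temporal centroid
    sum(t_i h_i)/sum(h_i)) is smaller is the early-peaked *explosiveness*
    component; the other is *accumulation*.  If the centroids tie, the
    component with the larger loading at the final sample is accumulation.
    """
    if model.k != 2:
        raise ValueError("component labeling requires a k=2 model")
    t = model.time_axis
    if t is None:
        t = np.arange(model.H.shape[1], dtype=float)
    cents = []
    for h in model.H:
        s = h.sum()
        cents.append((t * h).sum() / s if s > _EPS else np.inf)
    if np.isclose(cents[0], cents[1]):
        acc = int(np.argmax(model.H[:, -1]))   # tie: later-ending component
    else:
        acc = int(np.argmax(cents))
    labels = {acc: ACCUMULATION, 1 - acc: EXPLOSIVENESS}
    return replace(model, labels=labels)


def reconstruct_percentile_profiles(model: ComponentModel, low_pct: float = 10.0,
                                    high_pct: float = 90.0,
                                    subset: np.ndarray | None = None) -> dict:
    """Interpretation profiles: low/mean/high score on one component, mean on the other.

    For each component, three profiles are reconstructed using that
    component's score at its ``low_pct`` percentile, mean, and ``high_pct``
    percentile (linear-interpolation percentile definition) while the other
    component is held at its mean score.  ``subset`` restricts the trials
    used (e.g. one perspective condition).
    """
    if not model.labels:
        raise ValueError("label the model before reconstructing profiles")
    W = model.W if subset is None else model.W[np.asarray(subset)]
    if W.shape[0] == 0:
        raise ValueError("empty subset")
    out: dict[str, dict[str, np.ndarray]] = {}
    for label in (EXPLOSIVENESS, ACCUMULATION):
        i = model._index_of(label)
        j = 1 - i
        s = W[:, i]
        other_mean = W[:, j].mean()
        qs = {
            "low": float(np.percentile(s, low_pct)),
            "mean": float(s.mean()),
            "high": float(np.percentile(s, high_pct)),
        }
        out[label] = {
            name: q * model.H[i] + other_mean * model.H[j] for name, q in qs.items()
        }
    return out


def make_subprofiles(model: ComponentModel) -> dict[str, np.ndarray]:
    """Per-trial subprofiles: score_k x loading_k for each component.

    The two subprofiles of a trial sum exactly to that trial's model
    reconstruction (row of W H).
    """
    if not model.labels:
        raise ValueError("label the model before building subprofiles")
    return {
        label: np.outer(model.scores(label), model.loading(label))
        for label in (EXPLOSIVENESS, ACCUMULATION)
    }


def extract_scores_from_subprofiles(S: np.ndarray, rank1_tol: float = 1e-6):
    """Recover per-trial scores and the shared loading from a subprofile matrix.

    Each row of ``S`` should be a nonnegative multiple of one common loading
    vector; the dominant singular direction (sign-corrected to be
    nonnegative) estimates the loading and each trial's projection
    coefficient estimates its score, unique up to one global scale.  If the
    matrix is not numerically rank-1 a warning reports the achieved rank-1
    energy fraction.

    Returns ``(scores, loading, energy_fraction)``.
    """
    S = np.asarray(S, dtype=np.float64)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    h = Vt[0]
    if h.sum() < 0:
        h = -h
    h = np.clip(h, 0.0, None)
    nrm = np.linalg.norm(h)
    if nrm > 0:
        h = h / nrm
    total = float((sv ** 2).sum())
    energy = float(sv[0] ** 2 / total) if total > 0 else 1.0
    if energy < 1.0 - rank1_tol:
        logger.warning(
            "subprofile matrix is not rank-1: leading-direction energy fraction %.6f",
            energy,
        )
    scores = S @ h
    return scores, h, energy


# ---------------------------------------------------------------------------
# CSV I/O (scores, loadings, subprofiles)
# ---------------------------------------------------------------------------

def _require_index(model: ComponentModel) -> pd.DataFrame:
    if model.trial_index is None:
        raise ValueError("model has no trial index; fit from a ProfileMatrix")
    return model.trial_index


def write_scores_csv(model: ComponentModel, path: str | Path) -> None:
    table = _require_index(model).copy()
    table[EXPLOSIVENESS] = model.scores(EXPLOSIVENESS)
    table[ACCUMULATION] = model.scores(ACCUMULATION)
    table.to_csv(path, index=False)


def write_loadings_csv(model: ComponentModel, path: str | Path) -> None:
    t = model.time_axis
    if t is None:
        t = np.arange(model.H.shape[1], dtype=float)
    table = pd.DataFrame({"time_s": t})
    for label in (EXPLOSIVENESS, ACCUMULATION):
        table[label] = model.loading(label)
    table.to_csv(path, index=False)


def write_subprofiles_csv(model: ComponentModel, label: str, path: str | Path) -> None:
    """One row per trial, one column per time sample (plus the trial index)."""
    sub = make_subprofiles(model)[label]
    table = _require_index(model).copy()
    for j in range(sub.shape[1]):
        table[f"s{j:02d}"] = sub[:, j]
    table.to_csv(path, index=False)


def read_subprofiles_csv(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a subprofile CSV; returns (trial index, n_trials x n_samples array)."""
    table = pd.read_csv(path)
    sample_cols = [c for c in table.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    if not sample_cols:
        raise ValueError("no sample columns (s00, s01, ...) found")
    return table.drop(columns=sample_cols), table[sample_cols].to_numpy(float)
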