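"""First-level GLM design: boxcars, subprofile modulators, HRF, high-pass.

Each run is modeled with boxcar regressors for the perspective-instruction
screen, the 5 s feedback announcement, the two 90 s read-and-think epochs
(negative and neutral feedback) and the self-paced drawing period, with the
relaxation period left unmodeled as the implicit baseline.  The NNMF
subprofiles enter as two parametric regressors: each negative trial's
44-sample explosiveness (accumulation) subprofile is laid down across that
trial's 90 s epoch.  All task regressors are built on a microtime grid
(``microtime_bins_per_tr`` bins per TR), convolved with the canonical
double-gamma haemodynamic response function, and sampled at volume
midpoints.  Slow scanner drift is handled by a discrete-cosine high-pass
basis (cutoff 200 s), applied by projection (mathematically equivalent to
including the basis as nuisance columns in OLS); the six motion realignment
parameters are included as regressors of non-interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import EVENT_CLASSES, logger

__all__ = [
    "HRFSpec",
    "DesignMatrix",
    "CollinearityError",
    "canonical_hrf",
    "boxcar_regressor",
    "parametric_regressors",
    "dct_highpass_basis",
    "assemble_design",
    "project_out",
]

#: Boxcar-modeled event classes, in design-matrix column order.
TASK_CLASSES = (
    "perspective_instruction",
    "announce",
    "feedback_negative",
    "feedback_neutral",
    "drawing",
)

MOTION_NAMES = ("motion_tx", "motion_ty", "motion_tz",
                "motion_rx", "motion_ry", "motion_rz")


class CollinearityError(ValueError):
    """Raised when design columns are linearly dependent; names the offenders."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"collinear design columns: {columns}")


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma HRF parameters (SPM convention).

    The response is the difference of two gamma densities,
    ``g(t; peak) - g(t; undershoot) / peak_undershoot_ratio``, with shape
    ``delay / dispersion`` and scale ``dispersion`` for each lobe.  Defaults
    (6 / 16 s delays, unit dispersions, ratio 6, 32 s kernel) are the SPM
    canonical values; time is discretised at ``tr_s / microtime_bins_per_tr``.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length_s: float = 32.0
    microtime_bins_per_tr: int = 16

    def __post_init__(self) -> None:
        for name in ("peak_delay_s", "undershoot_delay_s", "peak_dispersion",
                     "undershoot_dispersion", "peak_undershoot_ratio",
                     "kernel_length_s", "microtime_bins_per_tr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _hrf_values(spec: HRFSpec, t: np.ndarray) -> np.ndarray:
    peak = stats.gamma.pdf(t, a=spec.peak_delay_s / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
    under = stats.gamma.pdf(t, a=spec.undershoot_delay_s / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    return peak - under / spec.peak_undershoot_ratio


def canonical_hrf(spec: HRFSpec = HRFSpec(), tr_s: float = 2.04) -> np.ndarray:
    """Sample the canonical HRF at microtime resolution, normalised to unit peak."""
    if tr_s <= 0:
        raise ValueError("non-positive TR")
    dt = tr_s / spec.microtime_bins_per_tr
    t = np.arange(0.0, spec.kernel_length_s + dt / 2, dt)
    kernel = _hrf_values(spec, t)
    if kernel.sum() * dt <= 0:
        raise ValueError("HRF kernel must integrate to a positive value")
    return kernel / kernel.max()


def _conv_kernel(spec: HRFSpec, tr_s: float) -> np.ndarray:
    """Kernel for bin-wise convolution: midpoint samples (second-order accurate)."""
    dt = tr_s / spec.microtime_bins_per_tr
    t = np.arange(dt / 2, spec.kernel_length_s, dt)
    kernel = _hrf_values(spec, t)
    # unit peak on a dense grid, so the scale is independent of the bin width
    dense_peak = _hrf_values(spec, np.linspace(0, spec.kernel_length_s, 8192)).max()
    return kernel / dense_peak


def _add_interval(signal: np.ndarray, a: float, b: float, value: float,
                  dt: float) -> None:
    """Add ``value`` over [a, b) seconds with fractional bin coverage."""
    fa, fb = a / dt, b / dt
    i0, i1 = int(np.floor(fa)), int(np.ceil(fb))
    for i in range(max(i0, 0), min(i1, len(signal))):
        cover = min(i + 1.0, fb) - max(float(i), fa)
        if cover > 0:
            signal[i] += value * cover


def _convolve_and_sample(micro_signal: np.ndarray, kernel: np.ndarray,
                         n_volumes: int, bins: int, dt: float) -> np.ndarray:
    """HRF-convolve a microtime signal and sample at volume midpoints.

    With bin-averaged signals and midpoint-sampled kernel, ``conv[i]``
    approximates the continuous convolution at ``(i + 1) dt`` to second
    order; volume midpoint ``(n + 1/2) TR`` is therefore index
    ``n bins + bins/2 - 1``.
    """
    conv = np.convolve(micro_signal, kernel)[: len(micro_signal)] * dt
    mid = np.arange(n_volumes) * bins + max(bins // 2 - 1, 0)
    return conv[mid]


def _microtime_grid(n_volumes: int, tr_s: float, spec: HRFSpec):
    bins = spec.microtime_bins_per_tr
    dt = tr_s / bins
    return n_volumes * bins, bins, dt


def boxcar_regressor(events: pd.DataFrame, event_class: str, n_volumes: int,
                     tr_s: float, spec: HRFSpec = HRFSpec()) -> np.ndarray | None:
    """Convolved boxcar column for one event class of one run.

    Returns ``None`` (logged) if the run has no events of the class.  Events
    reaching past the end of the run and zero-duration events are errors.
    """
    rows = events[events["event_class"] == event_class]
    if rows.empty:
        logger.info("boxcar_regressor: no %s events in run; column absent", event_class)
        return None
    n_micro, bins, dt = _microtime_grid(n_volumes, tr_s, spec)
    run_end = n_volumes * tr_s
    signal = np.zeros(n_micro)
    for onset, dur in rows[["onset_s", "duration_s"]].itertuples(index=False):
        if dur <= 0:
            raise ValueError(f"zero-duration {event_class} event at {onset:g} s")
        if onset + dur > run_end + 1e-9:
            raise ValueError(
                f"{event_class} event at {onset:g} s extends past run end ({run_end:g} s)"
            )
        _add_interval(signal, onset, onset + dur, 1.0, dt)
    return _convolve_and_sample(signal, _conv_kernel(spec, tr_s), n_volumes, bins, dt)


def parametric_regressors(sub_expl: np.ndarray, sub_acc: np.ndarray,
                          events: pd.DataFrame, n_volumes: int, tr_s: float,
                          spec: HRFSpec = HRFSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Convolved explosiveness and accumulation columns for one run.

    ``sub_expl`` and ``sub_acc`` hold one 44-sample subprofile per
    negative-feedback event of the run, in event order.  Sample ``i`` of a
    trial is held piecewise-constant on
    ``[onset + i*epoch/n, onset + (i+1)*epoch/n)`` at microtime resolution,
    all trials are concatenated into one column per component, then
    HRF-convolved and sampled at volume midpoints.
    """
    fb = events[events["event_class"] == "feedback_negative"].sort_values("onset_s")
    sub_expl = np.atleast_2d(np.asarray(sub_expl, float))
    sub_acc = np.atleast_2d(np.asarray(sub_acc, float))
    if len(fb) != sub_expl.shape[0] or len(fb) != sub_acc.shape[0]:
        raise ValueError(
            f"trial/event mismatch: {len(fb)} negative-feedback events, "
            f"{sub_expl.shape[0]}/{sub_acc.shape[0]} subprofile rows"
        )
    n_micro, bins, dt = _microtime_grid(n_volumes, tr_s, spec)
    kernel = _conv_kernel(spec, tr_s)
    cols = []
    for sub in (sub_expl, sub_acc):
        signal = np.zeros(n_micro)
        n_samp = sub.shape[1]
        for (onset, dur), values in zip(
                fb[["onset_s", "duration_s"]].itertuples(index=False), sub):
            step = dur / n_samp
            for i, v in enumerate(values):
                _add_interval(signal, onset + i * step, onset + (i + 1) * step,
                              v, dt)
        cols.append(_convolve_and_sample(signal, kernel, n_volumes, bins, dt))
    return cols[0], cols[1]


def dct_highpass_basis(n_volumes: int, tr_s: float,
                       cutoff_s: float = 200.0) -> np.ndarray:
    """Discrete-cosine drift basis: periods longer than ``cutoff_s``.

    Columns are ``cos(pi k (2n+1) / (2N))`` for ``k = 1..K`` with
    ``K = floor(2 N tr / cutoff)``; the constant (k=0) term is excluded, the
    intercept being a separate design column.  Columns are mutually
    orthogonal.
    """
    if n_volumes < 4:
        raise ValueError("need at least 4 volumes")
    if cutoff_s < 2 * tr_s:
        raise ValueError("high-pass cutoff shorter than 2 TR")
    N = n_volumes
    K = int(np.floor(2 * N * tr_s / cutoff_s))
    n = np.arange(N)
    return np.column_stack(
        [np.cos(np.pi * k * (2 * n + 1) / (2 * N)) for k in range(1, K + 1)]
    ) if K > 0 else np.zeros((N, 0))


def project_out(basis: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Residualise the columns of ``A`` against ``basis`` (OLS projection)."""
    if basis.shape[1] == 0:
        return A
    coef, *_ = np.linalg.lstsq(basis, A, rcond=None)
    return A - basis @ coef


@dataclass
class DesignMatrix:
    """A run's design: task + parametric + motion + intercept columns.

    The drift basis is stored separately in ``hp_basis`` and applied by
    projection during estimation; :meth:`full_matrix` returns the equivalent
    augmented matrix (task, parametric, motion, DCT, intercept) for
    inspection and export.
    """

    M: np.ndarray
    names: list[str]
    tr_s: float
    hp_basis: np.ndarray
    baseline_note: str = "relax period unmodeled (implicit baseline)"

    def __post_init__(self) -> None:
        if len(self.names) != self.M.shape[1]:
            raise ValueError("one name per column required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("column names must be unique")

    @property
    def n_volumes(self) -> int:
        return self.M.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.M[:, self.names.index(name)]

    def full_matrix(self) -> tuple[np.ndarray, list[str]]:
        dct_names = [f"dct{k:02d}" for k in range(1, self.hp_basis.shape[1] + 1)]
        i = self.names.index("intercept")
        M = np.column_stack([self.M[:, :i], self.hp_basis, self.M[:, i:]])
        return M, self.names[:i] + dct_names + self.names[i:]

    def to_csv(self, path) -> None:
        M, names = self.full_matrix()
        pd.DataFrame(M, columns=names).to_csv(path, index=False)


def _dependent_columns(M: np.ndarray, names: list[str],
                       rtol: float = 1e-8) -> list[str]:
    """Columns (scanned left to right) lying in the span of earlier columns."""
    bad = []
    for j in range(1, M.shape[1]):
        prev, col = M[:, :j], M[:, j]
        resid = col - prev @ np.linalg.lstsq(prev, col, rcond=None)[0]
        if np.linalg.norm(resid) < rtol * max(np.linalg.norm(col), 1e-30):
            bad.append(names[j])
    return bad


def assemble_design(events: pd.DataFrame, subprofiles: dict | None,
                    motion: np.ndarray | None, n_volumes: int, tr_s: float,
                    hp_cutoff_s: float = 200.0,
                    spec: HRFSpec = HRFSpec()) -> DesignMatrix:
    """Assemble one run's design matrix in canonical column order.

    ``subprofiles`` maps ``explosiveness`` / ``accumulation`` to the run's
    per-negative-trial 44-sample subprofile arrays; pass ``None`` for the
    boxcar-only model used by the perspective contrasts.  Column order is
    [5 task boxcars, explosiveness, accumulation, 6 motion, intercept] with
    the DCT drift basis carried alongside.  All-zero task columns and
    linearly dependent columns are errors.
    """
    cols, names = [], []
    for cls in TASK_CLASSES:
        col = boxcar_regressor(events, cls, n_volumes, tr_s, spec)
        if col is None:
            continue
        name = "instruction" if cls == "perspective_instruction" else cls
        cols.append(col)
        names.append(name)
    if subprofiles is not None:
        from .decomposition import ACCUMULATION, EXPLOSIVENESS
        expl, acc = parametric_regressors(
            subprofiles[EXPLOSIVENESS], subprofiles[ACCUMULATION],
            events, n_volumes, tr_s, spec)
        cols += [expl, acc]
        names += [EXPLOSIVENESS, ACCUMULATION]
    for name, col in zip(names, cols):
        if not np.any(np.abs(col) > 1e-12):
            raise ValueError(f"all-zero task column: {name}")
    if motion is not None:
        motion = np.asarray(motion, float)
        if motion.shape != (n_volumes, 6):
            raise ValueError(
                f"motion table must be {n_volumes} x 6, got {motion.shape}")
        cols += [motion[:, j] for j in range(6)]
        names += list(MOTION_NAMES)
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    M = np.column_stack(cols)
    bad = _dependent_columns(M, names)
    if bad:
        raise CollinearityError(bad)
    basis = dct_highpass_basis(n_volumes, tr_s, hp_cutoff_s)
    logger.info("design: %d volumes x %d columns (+%d drift), rank %d",
                M.shape[0], M.shape[1], basis.shape[1],
                np.linalg.matrix_rank(M))
    return DesignMatrix(M=M, names=names, tr_s=tr_s, hp_basis=basis)
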