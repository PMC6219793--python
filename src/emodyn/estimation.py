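"""First-level OLS, contrasts, random-effects group maps, ROI statistics.

Per run, the BOLD series is fit voxelwise by ordinary least squares after the
discrete-cosine drift basis has been projected out of both data and
regressors (equivalent to including the basis as nuisance columns).
Per-subject beta or contrast maps are carried to a random-effects group
analysis: a voxelwise one-sample t-test across subjects, thresholded at
p < .001 (uncorrected) with a 10-voxel extent rule, complemented by
Benjamini-Hochberg voxelwise FDR and familywise cluster correction.
Cluster-level FWER is computed by sign-flip permutation of the subject maps
(exact under a symmetric null) rather than random-field theory, which needs
smoothness estimates and large lattices.  ROI analyses average the
second-level betas over mask voxels and test them with one-sample t-tests,
one-sided in the hypothesised (positive) direction, Bonferroni-corrected for
the family of tests reported together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .design import DesignMatrix, project_out
from .io_core import StatMap, VolumeSeries, logger

__all__ = [
    "FirstLevelResult",
    "ROIResult",
    "fit_first_level",
    "contrast_map",
    "subject_beta_map",
    "group_ttest",
    "threshold_clusters",
    "fdr_voxelwise",
    "cluster_fwer_signflip",
    "group_cluster_analysis",
    "roi_mean_test",
    "split_insula_mask",
]


# ---------------------------------------------------------------------------
# First level
# ---------------------------------------------------------------------------

@dataclass
class FirstLevelResult:
    """Voxelwise OLS fit of one run."""

    beta: np.ndarray          # (n_inmask_voxels, n_regressors)
    sigma2: np.ndarray        # (n_inmask_voxels,) residual variance
    XtX_inv: np.ndarray       # (p, p) of the drift-filtered design
    df: int
    names: list[str]
    mask: np.ndarray          # 3-D boolean
    affine: np.ndarray

    def beta_map(self, name: str) -> np.ndarray:
        """3-D beta map of the named regressor (NaN outside the mask)."""
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = self.beta[:, self.names.index(name)]
        return vol


def fit_first_level(bold: VolumeSeries, design: DesignMatrix) -> FirstLevelResult:
    """Voxelwise OLS after projecting the drift basis out of data and design.

    Residual degrees of freedom account for the drift columns:
    ``df = n_volumes - rank(X) - n_drift``.
    """
    n = design.n_volumes
    if bold.n_volumes < n:
        raise ValueError(
            f"BOLD has {bold.n_volumes} volumes, design models {n}")
    if not bold.brain_mask.any():
        raise ValueError("empty brain mask")
    Y = bold.data[..., :n][bold.brain_mask].T        # (n, V)
    X = project_out(design.hp_basis, design.M)
    Y = project_out(design.hp_basis, Y)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    df = n - rank - design.hp_basis.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                          # (p, V)
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df
    logger.info("first level: %d volumes, %d regressors, %d voxels, df=%d",
                n, X.shape[1], Y.shape[1], df)
    return FirstLevelResult(beta=beta.T, sigma2=sigma2, XtX_inv=XtX_inv, df=df,
                            names=list(design.names), mask=bold.brain_mask,
                            affine=bold.affine)


def contrast_map(flr: FirstLevelResult, contrast) -> StatMap:
    """t-map of a linear contrast of first-level coefficients.

    ``contrast`` is either a length-p vector or a mapping from regressor
    name to weight (unnamed regressors get 0).
    """
    if isinstance(contrast, dict):
        c = np.zeros(len(flr.names))
        for name, w in contrast.items():
            c[flr.names.index(name)] = w
    else:
        c = np.asarray(contrast, float)
        if c.shape != (len(flr.names),):
            raise ValueError("contrast length must equal the number of regressors")
    if not np.any(c):
        raise ValueError("zero contrast vector")
    est = flr.beta @ c
    var = flr.sigma2 * float(c @ flr.XtX_inv @ c)
    t = est / np.sqrt(var)
    vol = np.full(flr.mask.shape, np.nan)
    vol[flr.mask] = t
    return StatMap(values=vol, kind="t", df=flr.df, affine=flr.affine,
                   mask=flr.mask.copy())


def subject_beta_map(results: list[FirstLevelResult], name: str) -> np.ndarray:
    """Average a regressor's beta maps over a subject's runs."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN out of mask
        return np.nanmean([r.beta_map(name) for r in results], axis=0)


# ---------------------------------------------------------------------------
# Group level
# ---------------------------------------------------------------------------

def _stack(maps) -> np.ndarray:
    data = np.stack([m.values if isinstance(m, StatMap) else np.asarray(m, float)
                     for m in maps])
    if data.ndim != 4:
        raise ValueError("need a stack of 3-D subject maps")
    return data


def group_ttest(maps, mask: np.ndarray | None = None):
    """Voxelwise one-sample t-test across subjects against zero.

    Returns ``(t, p_two_sided, p_one_sided)`` stat maps with
    ``df = n_subjects - 1``.  One-sided p is for the positive direction.
    Voxels with zero between-subject variance are excluded when the mean is
    also zero and flagged (p = 0) otherwise.
    """
    data = _stack(maps)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if mask is None:
        mask = np.all(np.isfinite(data), axis=0)
    else:
        mask = mask & np.all(np.isfinite(data), axis=0)
    vals = data[:, mask]
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    zero_sd = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = zero_sd & (mean != 0)
    if degenerate.any():
        logger.warning("group_ttest: %d zero-variance nonzero-mean voxels (p set to 0)",
                       int(degenerate.sum()))
        t[degenerate] = np.sign(mean[degenerate]) * np.inf
    drop = zero_sd & (mean == 0)
    if drop.any():
        logger.warning("group_ttest: %d all-zero voxels excluded", int(drop.sum()))
    df = n - 1
    p_two = 2 * stats.t.sf(np.abs(t), df)
    p_one = stats.t.sf(t, df)
    flat_idx = np.argwhere(mask)
    keep = ~drop
    out_mask = np.zeros_like(mask)
    out_mask[tuple(flat_idx[keep].T)] = True

    def _vol(stat):
        vol = np.full(mask.shape, np.nan)
        vol[out_mask] = stat[keep]
        return vol

    affine = maps[0].affine if isinstance(maps[0], StatMap) else np.eye(4)
    return (
        StatMap(_vol(t), "t", df, affine, out_mask),
        StatMap(_vol(p_two), "p", df, affine, out_mask),
        StatMap(_vol(p_one), "p", df, affine, out_mask),
    )


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def threshold_clusters(tmap: StatMap, p_unc: float = 0.001, k_extent: int = 10,
                       connectivity: int = 18) -> tuple[pd.DataFrame, np.ndarray]:
    """Threshold a t-map (one-sided, positive) and keep clusters of >= k voxels.

    Returns a cluster table sorted by size (descending) and the binary
    supra-threshold map of the retained clusters.
    """
    t_crit = stats.t.isf(p_unc, tmap.df)
    supra = np.where(tmap.mask, tmap.values, -np.inf) > t_crit
    labels, n_labels = ndimage.label(supra, _connectivity_structure(connectivity))
    rows = []
    keep = np.zeros_like(supra)
    for lab in range(1, n_labels + 1):
        voxels = labels == lab
        size = int(voxels.sum())
        if size < k_extent:
            continue
        keep |= voxels
        tvals = np.where(voxels, tmap.values, -np.inf)
        peak = np.unravel_index(np.nanargmax(tvals), tvals.shape)
        world = (tmap.affine @ np.array([*peak, 1.0]))[:3]
        rows.append({
            "cluster_id": lab, "n_voxels": size,
            "peak_t": float(tmap.values[peak]),
            "peak_i": peak[0], "peak_j": peak[1], "peak_k": peak[2],
            "peak_x_mm": world[0], "peak_y_mm": world[1], "peak_z_mm": world[2],
        })
    table = pd.DataFrame(rows, columns=[
        "cluster_id", "n_voxels", "peak_t", "peak_i", "peak_j", "peak_k",
        "peak_x_mm", "peak_y_mm", "peak_z_mm"])
    table = table.sort_values("n_voxels", ascending=False, ignore_index=True)
    return table, keep


def fdr_voxelwise(pmap: StatMap) -> StatMap:
    """Benjamini-Hochberg q-values over in-mask voxels."""
    p = pmap.values[pmap.mask]
    q = multipletests(p, method="fdr_bh")[1]
    vol = np.full(pmap.mask.shape, np.nan)
    vol[pmap.mask] = q
    return StatMap(vol, "q", pmap.df, pmap.affine, pmap.mask.copy())


def _max_cluster_size(t_vol: np.ndarray, mask: np.ndarray, t_crit: float,
                      structure: np.ndarray) -> int:
    supra = np.where(mask, t_vol, -np.inf) > t_crit
    if not supra.any():
        return 0
    labels, n_labels = ndimage.label(supra, structure)
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_fwer_signflip(maps, p_unc: float = 0.001, k_extent: int = 10,
                          n_perms: int = 1000, seed: int = 0,
                          connectivity: int = 18,
                          mask: np.ndarray | None = None):
    """Cluster-level FWER p-values by sign-flip permutation.

    Under the symmetric null, flipping each subject's map sign is an exact
    group symmetry; the max supra-threshold cluster size over random flips
    gives the null distribution, and each observed cluster gets
    ``p = (1 + #(perm max >= observed size)) / (1 + n_perms)``.
    """
    data = _stack(maps)
    n_sub = data.shape[0]
    if n_perms > 2 ** n_sub:
        raise ValueError(
            f"n_perms={n_perms} exceeds the {2**n_sub} distinct sign patterns "
            f"of {n_sub} subjects; enumerate the patterns exactly instead")
    tmap, _, _ = group_ttest(list(data), mask)
    table, keep = threshold_clusters(tmap, p_unc, k_extent, connectivity)
    structure = _connectivity_structure(connectivity)
    t_crit = stats.t.isf(p_unc, tmap.df)
    rng = np.random.default_rng(seed)
    flat = data[:, tmap.mask]
    n = flat.shape[0]
    max_sizes = np.empty(n_perms, dtype=int)
    t_vol = np.full(tmap.mask.shape, -np.inf)
    for b in range(n_perms):
        signs = rng.choice([-1.0, 1.0], size=n)
        vals = flat * signs[:, None]
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        t_vol[tmap.mask] = t
        max_sizes[b] = _max_cluster_size(t_vol, tmap.mask, t_crit, structure)
    table = table.copy()
    table["cluster_p_fwer"] = [
        (1 + int((max_sizes >= s).sum())) / (1 + n_perms)
        for s in table["n_voxels"]
    ]
    return table, keep, tmap


def group_cluster_analysis(maps, p_unc: float = 0.001, k_extent: int = 10,
                           connectivity: int = 18, n_perms: int = 1000,
                           seed: int = 0) -> pd.DataFrame:
    """Full group cluster table: extent-thresholded clusters with FWER and FDR.

    Combines the one-sample group t-map, extent thresholding, sign-flip
    cluster FWER and voxelwise BH-FDR (reported at each cluster peak).
    """
    table, _, tmap = cluster_fwer_signflip(
        maps, p_unc, k_extent, n_perms, seed, connectivity)
    _, _, p_one = group_ttest(maps)
    qmap = fdr_voxelwise(p_one)
    table["peak_q_fdr"] = [
        float(qmap.values[i, j, k])
        for i, j, k in table[["peak_i", "peak_j", "peak_k"]].itertuples(index=False)
    ]
    return table


# ---------------------------------------------------------------------------
# ROI analyses
# ---------------------------------------------------------------------------

@dataclass
class ROIResult:
    """One ROI x regressor mean-beta test (Bonferroni-corrected, one-sided)."""

    roi_name: str
    regressor: str
    mean_beta: float
    T: float
    df: int
    p_raw: float
    p_bonferroni: float
    n_tests_in_family: int


def roi_mean_test(maps, roi_mask: np.ndarray, roi_name: str, regressor: str,
                  n_tests_in_family: int = 1,
                  brain_mask: np.ndarray | None = None) -> ROIResult:
    """One-sample t-test of subjects' mean beta over an ROI.

    Per subject, betas are averaged across the ROI's (in-brain) voxels; the
    subject means are tested against zero, one-sided in the positive
    direction, and the p-value is Bonferroni-multiplied by the family size.
    A strongly negative effect therefore yields p at the ceiling of 1.
    """
    data = _stack(maps)
    roi = roi_mask.astype(bool)
    if brain_mask is not None:
        roi = roi & brain_mask
    if not roi.any():
        raise ValueError(f"ROI {roi_name!r} has no voxels inside the brain mask")
    subject_means = np.nanmean(data[:, roi], axis=1)
    n = len(subject_means)
    df = n - 1
    mean = float(subject_means.mean())
    sd = subject_means.std(ddof=1)
    if sd == 0:
        T = 0.0 if mean == 0 else np.sign(mean) * np.inf
    else:
        T = float(mean / (sd / np.sqrt(n)))
    p_raw = float(stats.t.sf(T, df))
    return ROIResult(roi_name=roi_name, regressor=regressor, mean_beta=mean,
                     T=T, df=df, p_raw=p_raw,
                     p_bonferroni=min(1.0, p_raw * n_tests_in_family),
                     n_tests_in_family=n_tests_in_family)


def split_insula_mask(mask: np.ndarray, affine: np.ndarray,
                      y_split_mm: float = -10.0) -> tuple[np.ndarray, np.ndarray]:
    """Split a mask at a world-space (MNI) y coordinate.

    Voxels whose center lies at y > ``y_split_mm`` go to the anterior mask,
    the rest (including y exactly at the split) to the posterior mask.
    """
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("empty mask")
    world_y = (np.column_stack([idx, np.ones(len(idx))]) @ affine.T)[:, 1]
    anterior = np.zeros_like(mask, dtype=bool)
    posterior = np.zeros_like(mask, dtype=bool)
    ant_sel = world_y > y_split_mm
    anterior[tuple(idx[ant_sel].T)] = True
    posterior[tuple(idx[~ant_sel].T)] = True
    for name, m in (("anterior", anterior), ("posterior", posterior)):
        if not m.any():
            logger.warning("split_insula_mask: %s side is empty", name)
    return anterior, posterior
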