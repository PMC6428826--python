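"""Smoothness estimation, GRF cluster inference, specificity metrics and
group-level models.

Cluster-level multiple-comparison correction follows the classical
Gaussian-random-field recipe used by FSL's ``cluster``: image roughness
(DLH) and mask volume are estimated from the 4D residual maps, candidate
clusters are formed at a cluster-defining z threshold (default 3.09, the
99.9% standard-normal quantile), and each cluster's corrected p combines
the expected cluster count with an exponential cluster-size tail.  All
testing is one-sided.

Specificity metrics mirror the evaluation battery: the percentage of
in-mask voxels covered by significant clusters and the positive rate
(proportion of subjects with at least one significant cluster; on null
data this is the familywise error rate), with the Bernoulli confidence
band 0.05 +/- sqrt(0.05*0.95/n) around the nominal level.

Two group models are provided: the summary-statistic approach (voxel-wise
one-sample t on first-level coefficients) and a precision-weighted
mixed-effects model using first-level standard-error maps with a REML
between-subject variance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import VolumeSeries
from .whiten import t_to_z

logger = logging.getLogger(__name__)

FOUR_LN2 = 4.0 * math.log(2.0)
#: z value forming candidate clusters: the 99.9% standard-normal quantile
DEFAULT_CDT = 3.09


@dataclass
class SmoothnessEstimate:
    """Residual-map smoothness: per-axis FWHM (mm), DLH, volume, resels."""

    fwhm_mm: np.ndarray
    fwhm_vox: np.ndarray
    dlh: float
    volume: int
    resels: float

    @property
    def geometric_mean_fwhm_mm(self) -> float:
        return float(np.prod(self.fwhm_mm) ** (1.0 / 3.0))


@dataclass
class ClusterResult:
    """Clusters above the CDT with GRF-corrected p-values.

    ``sig_mask`` is the union of clusters with corrected p <= alpha.
    """

    clusters: pd.DataFrame  # size_vox, peak_z, p_corrected, peak_x/y/z
    sig_mask: np.ndarray
    cdt: float
    alpha: float

    @property
    def n_significant(self) -> int:
        return int((self.clusters["p_corrected"] <= self.alpha).sum())

    @property
    def any_significant(self) -> bool:
        return self.n_significant > 0

    def to_tsv(self, path) -> None:
        self.clusters.to_csv(path, sep="\t", index=True, index_label="index")


@dataclass
class PositiveRateResult:
    """Proportion of subjects with >= 1 significant cluster, with the
    Bernoulli band around the nominal 5% level."""

    rate: float
    n: int
    ci_low: float
    ci_high: float

    @property
    def within_band(self) -> bool:
        return self.ci_low <= self.rate <= self.ci_high


def _axis_rho(std_resid: np.ndarray, mask: np.ndarray, axis: int) -> float:
    """Pooled lag-1 spatial correlation of standardized residuals along axis."""
    sl_a = [slice(None)] * 3
    sl_b = [slice(None)] * 3
    sl_a[axis] = slice(None, -1)
    sl_b[axis] = slice(1, None)
    pair = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    if not pair.any():
        return 0.0
    xa = std_resid[tuple(sl_a)][pair]
    xb = std_resid[tuple(sl_b)][pair]
    num = float(np.einsum("vt,vt->", xa, xb))
    den = 0.5 * (float(np.einsum("vt,vt->", xa, xa))
                 + float(np.einsum("vt,vt->", xb, xb)))
    return num / den if den > 0 else 0.0


def estimate_smoothness(residuals4d: VolumeSeries,
                        mask: np.ndarray | None = None,
                        voxel_size: tuple = (1.0, 1.0, 1.0)) -> SmoothnessEstimate:
    """Estimate residual smoothness from 4D residual maps.

    Residual series are standardized voxel-wise; the pooled lag-1
    spatial correlation ``rho`` along each axis is converted to a
    Gaussian-kernel FWHM via ``sigma^2 = -1/(4 ln rho)`` (voxel units),
    averaged over time.  DLH is ``(4 ln 2)^{3/2}`` divided by the FWHM
    product in voxels; resels = mask volume / FWHM product.

    An unsmoothed (spatially independent) field has rho ~ 0 and
    estimated FWHM near zero; rho is floored so the estimate stays
    finite.
    """
    mask = residuals4d.mask if mask is None else np.asarray(mask, dtype=bool)
    data = residuals4d.data
    if data.shape[3] < 2:
        raise ValueError("need at least 2 time points of residuals")
    if not mask.any():
        raise ValueError("empty mask")
    R = data[mask]
    sd = R.std(axis=1, keepdims=True)
    if np.all(sd == 0):
        raise ValueError("all-constant residuals: smoothness is undefined")
    ok = sd[:, 0] > 0
    std = np.zeros_like(R)
    std[ok] = (R[ok] - R[ok].mean(axis=1, keepdims=True)) / sd[ok]
    vol = np.zeros(mask.shape + (data.shape[3],))
    vol[mask] = std
    fwhm_vox = np.empty(3)
    for axis in range(3):
        rho = _axis_rho(vol, mask, axis)
        rho = min(max(rho, 1e-6), 1 - 1e-12)
        sigma2 = -1.0 / (4.0 * math.log(rho))
        fwhm_vox[axis] = math.sqrt(8.0 * math.log(2.0) * sigma2)
    fwhm_mm = fwhm_vox * np.asarray(voxel_size, dtype=float)
    prod = float(np.prod(fwhm_vox))
    volume = int(mask.sum())
    dlh = FOUR_LN2 ** 1.5 / prod
    resels = volume / prod
    return SmoothnessEstimate(fwhm_mm=fwhm_mm, fwhm_vox=fwhm_vox, dlh=dlh,
                              volume=volume, resels=resels)


def smoothness_from_fwhm(fwhm_vox, volume: int,
                         voxel_size: tuple = (1.0, 1.0, 1.0)) -> SmoothnessEstimate:
    """Build a SmoothnessEstimate from known per-axis FWHM (voxel units)."""
    fwhm_vox = np.broadcast_to(np.asarray(fwhm_vox, dtype=float), (3,)).copy()
    prod = float(np.prod(fwhm_vox))
    return SmoothnessEstimate(fwhm_mm=fwhm_vox * np.asarray(voxel_size),
                              fwhm_vox=fwhm_vox,
                              dlh=FOUR_LN2 ** 1.5 / prod, volume=volume,
                              resels=volume / prod)


def _expected_clusters(resels: float, u: float) -> float:
    """Expected number of clusters above u in a 3D Gaussian field (EC density)."""
    return (resels * FOUR_LN2 ** 1.5 * (2 * math.pi) ** -2
            * (u * u - 1.0) * math.exp(-u * u / 2.0))


def grf_cluster_inference(zmap: np.ndarray, mask: np.ndarray,
                          smooth: SmoothnessEstimate,
                          cdt: float = DEFAULT_CDT,
                          alpha: float = 0.05) -> ClusterResult:
    """One-sided GRF cluster-level inference on a z-statistic map.

    Connected components (26-connectivity) of ``z >= cdt`` within the
    mask are assessed against the expected cluster count E[m] and the
    exponential cluster-size tail ``P(S >= s) = exp(-beta s^{2/3})``
    with ``beta = (Gamma(5/2) E[m] / E[N])^{2/3}`` (E[N] = expected
    suprathreshold voxel count); corrected
    ``p = 1 - exp(-E[m] P(S >= s))``.
    """
    if not cdt > 0:
        raise ValueError("cdt must be positive (one-sided inference)")
    if not smooth.resels > 0:
        raise ValueError("zero resels: smoothness estimate is degenerate")
    zmap = np.asarray(zmap, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    supra = (zmap >= cdt) & mask
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n_clusters = ndimage.label(supra, structure=structure)
    em = _expected_clusters(smooth.resels, cdt)
    en = smooth.volume * float(stats.norm.sf(cdt))
    rows = []
    sig_mask = np.zeros(mask.shape, dtype=bool)
    if n_clusters and em > 0 and en > 0:
        beta = (math.gamma(2.5) * em / en) ** (2.0 / 3.0)
        sizes = ndimage.sum_labels(np.ones_like(zmap), labels,
                                   index=np.arange(1, n_clusters + 1))
        peaks = ndimage.maximum_position(zmap, labels,
                                         index=np.arange(1, n_clusters + 1))
        for ci, (size, peak) in enumerate(zip(sizes, peaks), start=1):
            p_tail = math.exp(-beta * size ** (2.0 / 3.0))
            p_corr = -math.expm1(-em * p_tail)
            rows.append({"size_vox": int(size),
                         "peak_z": float(zmap[peak]),
                         "p_corrected": p_corr,
                         "peak_x": peak[0], "peak_y": peak[1], "peak_z_idx": peak[2]})
            if p_corr <= alpha:
                sig_mask |= labels == ci
    clusters = pd.DataFrame(rows, columns=["size_vox", "peak_z", "p_corrected",
                                           "peak_x", "peak_y", "peak_z_idx"])
    if len(clusters):
        clusters = clusters.sort_values("size_vox", ascending=False,
                                        ignore_index=True)
    return ClusterResult(clusters=clusters, sig_mask=sig_mask, cdt=cdt,
                         alpha=alpha)


def percent_significant(sig_mask: np.ndarray, mask: np.ndarray) -> float:
    """Percentage of in-mask voxels covered by significant clusters."""
    mask = np.asarray(mask, dtype=bool)
    sig_mask = np.asarray(sig_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if np.any(sig_mask & ~mask):
        raise ValueError("sig_mask must be a subset of mask")
    return 100.0 * sig_mask.sum() / mask.sum()


def positive_rate(per_subject_results: list,
                  nominal: float = 0.05) -> PositiveRateResult:
    """Proportion of subjects with at least one significant cluster.

    The confidence band around the nominal level uses the Bernoulli
    variance: ``nominal +/- sqrt(nominal*(1-nominal)/n)``.
    """
    n = len(per_subject_results)
    if n < 1:
        raise ValueError("need at least one subject")
    hits = sum(1 for r in per_subject_results if r.any_significant)
    half = math.sqrt(nominal * (1 - nominal) / n)
    return PositiveRateResult(rate=hits / n, n=n,
                              ci_low=nominal - half, ci_high=nominal + half)


#: z magnitude assigned at zero-between-subject-variance voxels
_DEGENERATE_Z = 38.0


def group_summary_statistic(coef_maps: np.ndarray) -> np.ndarray:
    """Summary-statistic group model: voxel-wise one-sample t, t -> z.

    ``coef_maps`` is ``(n_subjects, n_voxels)`` of first-level task
    coefficients.  Voxels with zero between-subject variance and
    nonzero mean are flagged and assigned ``sign(mean) * 38`` (the tail
    convention; z of that magnitude is beyond float representation of
    the p-value anyway).
    """
    Y = np.asarray(coef_maps, dtype=float)
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    df = n - 1
    degen = sd == 0
    if degen.any():
        logger.info("zero between-subject variance at %d voxels", int(degen.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~degen, mean / (sd / math.sqrt(n) + (sd == 0)), 0.0)
    z = t_to_z(t, df)
    z[degen] = np.sign(mean[degen]) * _DEGENERATE_Z
    return z


def group_mixed_effects(coef_maps: np.ndarray, se_maps: np.ndarray,
                        max_iter: int = 50, tol: float = 1e-8) -> np.ndarray:
    """Precision-weighted mixed-effects group model.

    Per voxel, subjects are combined with weights ``1/(se_i^2 + tau^2)``
    where the between-subject variance ``tau^2 >= 0`` is estimated by
    the REML fixed-point iteration (DerSimonian-Laird fallback, logged,
    for voxels that fail to converge).  The weighted-mean statistic is
    referred to t with df = n-1 and converted to z.
    """
    Y = np.asarray(coef_maps, dtype=float)
    V = np.asarray(se_maps, dtype=float) ** 2
    if Y.shape != V.shape:
        raise ValueError("coef and se maps must have equal shape")
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.any(V <= 0):
        raise ValueError("standard errors must be positive on the mask")
    tau2 = np.maximum(Y.var(axis=0, ddof=1) - V.mean(axis=0), 0.0)
    converged = np.zeros(Y.shape[1], dtype=bool)
    for _ in range(max_iter):
        w = 1.0 / (V + tau2)
        sw = w.sum(axis=0)
        mu = (w * Y).sum(axis=0) / sw
        num = (w**2 * ((Y - mu) ** 2 - V)).sum(axis=0)
        tau2_new = np.maximum(num / (w**2).sum(axis=0) + 1.0 / sw, 0.0)
        converged = np.abs(tau2_new - tau2) <= tol * (tau2 + 1.0)
        tau2 = tau2_new
        if converged.all():
            break
    if not converged.all():
        # method-of-moments (DerSimonian-Laird) fallback
        idx = ~converged
        logger.info("REML tau^2 not converged at %d voxels; DL fallback",
                    int(idx.sum()))
        w0 = 1.0 / V[:, idx]
        mu0 = (w0 * Y[:, idx]).sum(axis=0) / w0.sum(axis=0)
        q = (w0 * (Y[:, idx] - mu0) ** 2).sum(axis=0)
        denom = w0.sum(axis=0) - (w0**2).sum(axis=0) / w0.sum(axis=0)
        tau2[idx] = np.maximum((q - (n - 1)) / denom, 0.0)
    w = 1.0 / (V + tau2)
    sw = w.sum(axis=0)
    mu = (w * Y).sum(axis=0) / sw
    t = mu * np.sqrt(sw)
    return t_to_z(t, n - 1)
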