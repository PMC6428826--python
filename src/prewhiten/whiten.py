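"""Temporal autocorrelation estimation and pre-whitened GLM refitting.

Implements the four noise-model families whose whitening behaviour the
package evaluates:

* ``afni_arma11`` — voxel-wise ARMA(1,1), parameters estimated on a
  discrete grid by exact Gaussian profile likelihood (no spatial
  smoothing of the parameters);
* ``fsl_tukey``  — voxel-wise sample autocorrelation shrunk by a Tukey
  (cosine) lag window and truncated at lag M;
* ``spm_ar1wn``  — a single global AR(1)-plus-white-noise model:
  two-component ReML (identity + AR(1) kernel at a fixed coefficient),
  fitted on a pooled voxel selection;
* ``fast``       — a global ReML mixture over a dictionary of 3p
  exponential covariance components (p time constants, each with its
  first and second derivatives with respect to the inverse time
  constant; 18 components at the default p=6).

Each model yields a T x T covariance V and a whitening transform W with
``W V W' = I`` (inverse-Cholesky convention); ``prewhitened_glm``
pre-whitens both the data and the design and refits by OLS, producing
the t/z maps and whitened residuals used downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, special, stats

from .core import VolumeSeries
from .design import DesignMatrix

logger = logging.getLogger(__name__)

METHODS = ("none", "spm_ar1wn", "afni_arma11", "fsl_tukey", "fast")

#: fixed AR coefficient of the AR(1) kernel in the global AR(1)+WN model
SPM_AR_COEF = 0.2
#: relative eigenvalue floor used when a covariance is not positive definite
PD_FLOOR = 1e-6
#: ReML iteration cap and relative log-likelihood convergence tolerance
REML_MAXITER = 64
REML_TOL = 1e-6


# ---------------------------------------------------------------------------
# model containers


@dataclass
class NoiseModel:
    """A fitted temporal autocovariance description.

    ``scope='global'`` models hold a single autocorrelation sequence
    ``acf`` of shape (T,); ``scope='voxelwise'`` models hold one row per
    voxel, shape (n_voxels, T).  ``acf[..., 0] == 1`` always.
    """

    method: str
    scope: str
    acf: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.scope not in ("global", "voxelwise"):
            raise ValueError("scope must be 'global' or 'voxelwise'")
        self.acf = np.atleast_1d(np.asarray(self.acf, dtype=float))
        lag0 = self.acf[..., 0]
        if not np.allclose(lag0, 1.0):
            raise ValueError("acf must be normalized to acf[0] = 1")

    @property
    def n_timepoints(self) -> int:
        return self.acf.shape[-1]

    def covariance(self, n_timepoints: int | None = None,
                   voxel: int | None = None) -> np.ndarray:
        """T x T correlation matrix implied by the (per-voxel) ACF."""
        acf = self.acf if self.scope == "global" else self.acf[voxel]
        T = n_timepoints or acf.size
        r = np.zeros(T)
        r[: min(T, acf.size)] = acf[:T]
        return linalg.toeplitz(r)

    def to_json_dict(self, n_head: int = 10) -> dict:
        head = (self.acf if self.scope == "global" else self.acf.mean(axis=0))
        return {
            "method": self.method,
            "scope": self.scope,
            "acf_head": [float(v) for v in head[:n_head]],
            "params": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.params.items()},
        }


def identity_model(n_timepoints: int) -> NoiseModel:
    """The 'no pre-whitening' model (V = I)."""
    acf = np.zeros(n_timepoints)
    acf[0] = 1.0
    return NoiseModel(method="none", scope="global", acf=acf)


@dataclass
class GLMFit:
    """Per-voxel GLM results on the (possibly whitened) design.

    ``residuals`` are the residuals of the fit actually performed — for a
    pre-whitened fit these are the whitened residuals whose power
    spectra the diagnostics display.
    """

    coefficients: np.ndarray      # (n_voxels, K)
    residuals: np.ndarray         # (n_voxels, T)
    tmap: np.ndarray | None       # (n_voxels,) task contrast t, None for rest
    zmap: np.ndarray | None
    se_map: np.ndarray | None
    df: float
    whitened: bool
    design: DesignMatrix
    sigma2: np.ndarray = None     # type: ignore[assignment]  # residual variance

    @property
    def n_voxels(self) -> int:
        return self.residuals.shape[0]


# ---------------------------------------------------------------------------
# OLS and GLS fitting


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, VolumeSeries):
        return data.to_matrix()
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def _fit_matrix(Y: np.ndarray, Xw: np.ndarray, X0: DesignMatrix,
                whitened: bool) -> GLMFit:
    """OLS of rows of Y on Xw; contrast/roles taken from X0."""
    T, K = Xw.shape
    rank = np.linalg.matrix_rank(Xw)
    if rank < K:
        raise ValueError("rank-deficient design matrix")
    pinv = np.linalg.pinv(Xw)
    beta = Y @ pinv.T
    resid = Y - beta @ Xw.T
    df = T - rank
    sigma2 = np.einsum("vt,vt->v", resid, resid) / df
    c = X0.task_contrast
    tmap = zmap = se_map = None
    if c is not None:
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
        cvar = float(c @ xtx_inv @ c)
        se_map = np.sqrt(np.maximum(sigma2 * cvar, 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tmap = np.where(se_map > 0, (beta @ c) / se_map, 0.0)
        zmap = t_to_z(tmap, df)
    return GLMFit(coefficients=beta, residuals=resid, tmap=tmap, zmap=zmap,
                  se_map=se_map, df=df, whitened=whitened, design=X0,
                  sigma2=sigma2)


def fit_ols(data, X: DesignMatrix) -> GLMFit:
    """Per-voxel ordinary least squares fit.

    ``data`` may be a VolumeSeries (in-mask voxels are used) or a
    ``(n_voxels, T)`` array.
    """
    Y = _as_matrix(data)
    if Y.shape[1] != X.n_timepoints:
        raise ValueError("data T does not match design T")
    if Y.shape[0] == 0:
        raise ValueError("mask is empty")
    return _fit_matrix(Y, X.matrix, X, whitened=False)


# ---------------------------------------------------------------------------
# whitening transforms


def whitening_from_covariance(V: np.ndarray) -> np.ndarray:
    """W = L^{-1} for V = L L' (lower Cholesky), so that W V W' = I."""
    V = np.asarray(V, dtype=float)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        V = _pd_floor(V)
        L = linalg.cholesky(V, lower=True)
    T = V.shape[0]
    return linalg.solve_triangular(L, np.eye(T), lower=True)


def _pd_floor(V: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at PD_FLOOR x the largest (tapered ACFs need not be PD)."""
    w, U = np.linalg.eigh(V)
    floor = PD_FLOOR * w.max()
    if w.max() <= 0:
        raise linalg.LinAlgError("covariance has no positive eigenvalue")
    w = np.maximum(w, floor)
    return (U * w) @ U.T


def build_whitening_matrix(model: NoiseModel, n_timepoints: int,
                           voxel: int | None = None) -> np.ndarray:
    """Whitening transform for a (per-voxel) noise model."""
    V = model.covariance(n_timepoints, voxel=voxel)
    return whitening_from_covariance(V)


def prewhitened_glm(data, X: DesignMatrix, model: NoiseModel) -> GLMFit:
    """Pre-whiten both the data and the design, then refit.

    For ``scope='global'`` one whitening matrix is applied to all voxels;
    for ``scope='voxelwise'`` each voxel is whitened with its own model
    (voxels sharing an identical ACF are batched).
    """
    Y = _as_matrix(data)
    T = X.n_timepoints
    if Y.shape[1] != T:
        raise ValueError("data T does not match design T")
    if model.method == "none":
        return fit_ols(Y, X)
    if model.scope == "global":
        W = build_whitening_matrix(model, T)
        return _fit_matrix(Y @ W.T, W @ X.matrix, X, whitened=True)

    if model.acf.shape[0] != Y.shape[0]:
        raise ValueError("voxelwise model has wrong number of voxels")
    n_vox, K = Y.shape[0], X.n_columns
    beta = np.empty((n_vox, K))
    resid = np.empty((n_vox, T))
    sigma2 = np.empty(n_vox)
    se_map = np.empty(n_vox)
    c = X.task_contrast
    df = None
    # batch voxels with identical ACF rows (e.g. shared ARMA grid cell)
    _, inverse = np.unique(np.round(model.acf, 12), axis=0, return_inverse=True)
    for g in np.unique(inverse):
        idx = np.where(inverse == g)[0]
        W = build_whitening_matrix(model, T, voxel=int(idx[0]))
        sub = _fit_matrix(Y[idx] @ W.T, W @ X.matrix, X, whitened=True)
        beta[idx] = sub.coefficients
        resid[idx] = sub.residuals
        sigma2[idx] = sub.sigma2
        if c is not None:
            se_map[idx] = sub.se_map
        df = sub.df
    tmap = zmap = None
    se_out = None
    if c is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            tmap = np.where(se_map > 0, (beta @ c) / se_map, 0.0)
        zmap = t_to_z(tmap, df)
        se_out = se_map
    return GLMFit(coefficients=beta, residuals=resid, tmap=tmap, zmap=zmap,
                  se_map=se_out, df=df, whitened=True, design=X, sigma2=sigma2)


# ---------------------------------------------------------------------------
# t -> z


def t_to_z(tmap: np.ndarray, df: float) -> np.ndarray:
    """Quantile-matching t-to-z transform, stable in the far tails.

    ``z = Phi^{-1}(F_t(t; df))`` computed through log survival
    probabilities (``ndtri_exp``) separately per sign so |t| up to ~40
    maps without saturation; strictly increasing and sign-preserving.
    """
    if not df > 0:
        raise ValueError("df must be positive")
    t = np.asarray(tmap, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    with np.errstate(divide="ignore"):
        z[pos] = -special.ndtri_exp(stats.t.logsf(t[pos], df))
        z[~pos] = special.ndtri_exp(stats.t.logcdf(t[~pos], df))
    return z


# ---------------------------------------------------------------------------
# ARMA(1,1): closed-form ACF and exact banded profile likelihood


def arma_acf(a: float, b: float, nlags: int) -> np.ndarray:
    """Closed-form ARMA(1,1) autocorrelation, lags 0..nlags-1."""
    rho = np.empty(nlags)
    rho[0] = 1.0
    if nlags > 1:
        rho1 = (1 + a * b) * (a + b) / (1 + 2 * a * b + b * b)
        # geometric decay at rate a beyond lag 1
        rho[1:] = rho1 * a ** np.arange(nlags - 1, dtype=float)
    return rho


def _arma_banded(a: float, b: float, T: int) -> np.ndarray:
    """Banded (upper 'ab' form) covariance of the AR(1)-filtered series.

    With unit innovations, z_1 = y_1 and z_t = y_t - a*y_{t-1} for t>1
    has a tridiagonal covariance: Var(z_1) = gamma_0, Cov(z_1,z_2) =
    gamma_1 - a*gamma_0, interior Var = 1+b^2, Cov = b, and zero beyond
    lag 1.  The filter is unit lower triangular, so the transformation
    leaves the Gaussian likelihood unchanged.
    """
    g0 = (1 + 2 * a * b + b * b) / (1 - a * a)
    g1 = (1 + a * b) * (a + b) / (1 - a * a)
    ab = np.zeros((2, T))
    ab[1, 0] = g0
    ab[1, 1:] = 1 + b * b
    ab[0, 1] = g1 - a * g0
    ab[0, 2:] = b
    return ab


def _ar_filter(a: float, M: np.ndarray) -> np.ndarray:
    """Apply the unit lower-bidiagonal AR(1) filter along axis 0."""
    Z = np.empty_like(M)
    Z[0] = M[0]
    Z[1:] = M[1:] - a * M[:-1]
    return Z


def arma_profile_loglik(resid: np.ndarray, a: float, b: float,
                        X: np.ndarray | None = None) -> np.ndarray:
    """Exact Gaussian (RE)ML log likelihood, innovation variance profiled out.

    ``resid`` is ``(n_voxels, T)`` (or 1D) of OLS residuals.  With
    ``X`` given, the restricted likelihood is evaluated: it accounts
    for the fixed effects projected out of the residuals (the term
    ``logdet(X' V^{-1} X)`` plus the GLS quadratic form, computable
    from OLS residuals alone because the GLS annihilator kills X).
    Without ``X``, the plain profile likelihood of the series.
    Values are comparable across (a, b) up to a shared constant.
    """
    R = np.atleast_2d(np.asarray(resid, dtype=float)).T  # (T, n_vox)
    T = R.shape[0]
    ab = _arma_banded(a, b, T)
    cb = linalg.cholesky_banded(ab, lower=False)
    logdet = 2.0 * np.log(cb[1]).sum()
    FR = _ar_filter(a, R)
    W = linalg.cho_solve_banded((cb, False), FR)  # B^{-1} F r
    q = np.einsum("tv,tv->v", FR, W)              # r' V^{-1} r
    if X is None:
        ll = -0.5 * logdet - 0.5 * T * np.log(q / T)
    else:
        K = X.shape[1]
        FX = _ar_filter(a, np.asarray(X, dtype=float))
        U = linalg.cho_solve_banded((cb, False), FX)
        G = FX.T @ U                               # X' V^{-1} X
        _, logdet_g = np.linalg.slogdet(G)
        XtViR = FX.T @ W                           # (K, n_vox)
        beta = linalg.solve(G, XtViR, assume_a="pos")
        q = q - np.einsum("kv,kv->v", XtViR, beta)  # GLS residual quad form
        df = T - K
        ll = -0.5 * (logdet + logdet_g) - 0.5 * df * np.log(q / df)
    return ll if resid.ndim > 1 else ll[0]


def estimate_afni_arma11(fit: GLMFit, grid_step: float = 0.05,
                         max_coef: float = 0.9,
                         null_lrt_alpha: float = 0.01) -> NoiseModel:
    """Voxel-wise ARMA(1,1) estimated on a discrete parameter grid.

    For every voxel the pair (a, b) maximizing the exact Gaussian REML
    likelihood of the OLS residuals (restricted for the design columns
    projected out of them) is selected from the grid
    ``{0, ±step, ..., ±max_coef}^2``; parameters are not spatially
    smoothed.  Returns a voxelwise model whose ACF follows the ARMA
    recursion at the selected grid point.

    ARMA(1,1) contains an exact white-noise ridge (b = -a cancels the AR
    pole), so under white noise the per-voxel grid maximum scatters along
    the ridge and its neighbourhood.  A parsimony guard keeps (0, 0)
    unless the grid maximum improves on the white model beyond the
    chi-square(2) likelihood-ratio quantile at ``null_lrt_alpha``
    (set ``null_lrt_alpha=1`` for the raw grid argmax).
    """
    if not 0 < grid_step <= 0.2:
        raise ValueError("grid_step must lie in (0, 0.2]")
    R = fit.residuals
    X = fit.design.matrix
    n_vox, T = R.shape
    n = int(round(max_coef / grid_step))
    axis = np.concatenate([np.arange(-n, 0), np.arange(0, n + 1)]) * grid_step
    axis = np.sort(axis)
    best_ll = np.full(n_vox, -np.inf)
    best_a = np.zeros(n_vox)
    best_b = np.zeros(n_vox)
    ll_origin = None
    for a in axis:
        for b in axis:
            ll = arma_profile_loglik(R, float(a), float(b), X=X)
            if a == 0 and b == 0:
                ll_origin = ll
            upd = ll > best_ll
            best_ll[upd] = ll[upd]
            best_a[upd] = a
            best_b[upd] = b
    if null_lrt_alpha < 1:
        crit = stats.chi2.isf(null_lrt_alpha, df=2) / 2.0
        keep_white = best_ll - ll_origin <= crit
        best_a[keep_white] = 0.0
        best_b[keep_white] = 0.0
    acf = np.empty((n_vox, T))
    pairs = set(zip(best_a.tolist(), best_b.tolist()))
    for a, b in pairs:
        sel = (best_a == a) & (best_b == b)
        acf[sel] = arma_acf(a, b, T)
    return NoiseModel(method="afni_arma11", scope="voxelwise", acf=acf,
                      params={"a": best_a, "b": best_b,
                              "grid_step": grid_step, "max_coef": max_coef})


# ---------------------------------------------------------------------------
# FSL-style Tukey taper


def tukey_window(n_lags: int, taper_m: int) -> np.ndarray:
    """Tukey lag window w(k) = 0.5*(1 + cos(pi*k/M)) for k < M, else 0."""
    k = np.arange(n_lags)
    w = np.where(k < taper_m, 0.5 * (1 + np.cos(np.pi * k / taper_m)), 0.0)
    return w


def default_taper_m(n_timepoints: int) -> int:
    """Classic lag-window rule M = floor(2*sqrt(T))."""
    return int(math.floor(2 * math.sqrt(n_timepoints)))


def sample_acf(series: np.ndarray, n_lags: int) -> np.ndarray:
    """Biased sample autocorrelation of each row, lags 0..n_lags-1 (FFT)."""
    X = np.atleast_2d(np.asarray(series, dtype=float))
    X = X - X.mean(axis=1, keepdims=True)
    T = X.shape[1]
    nfft = int(2 ** math.ceil(math.log2(2 * T)))
    F = np.fft.rfft(X, nfft, axis=1)
    ac = np.fft.irfft(F * np.conj(F), nfft, axis=1)[:, :n_lags]
    ac /= ac[:, :1]
    return ac if series.ndim > 1 else ac[0]


def estimate_fsl_tukey(fit: GLMFit, taper_m: int | None = None,
                       smooth_fwhm_vox: float = 0.0,
                       mask: np.ndarray | None = None) -> NoiseModel:
    """Voxel-wise Tukey-tapered autocorrelation estimate.

    The per-voxel sample ACF of the OLS residuals is multiplied by the
    cosine lag window and truncated at lag M (default
    ``floor(2*sqrt(T))``).  Optional within-mask spatial smoothing of
    the tapered ACF (off by default — synthetic data has a single
    tissue class) mimics the within-tissue smoothing stage.
    """
    R = fit.residuals
    n_vox, T = R.shape
    if taper_m is None:
        taper_m = default_taper_m(T)
    if not 2 <= taper_m < T:
        raise ValueError("taper_m must satisfy 2 <= M < T")
    acf = sample_acf(R, T)
    acf *= tukey_window(T, taper_m)
    if smooth_fwhm_vox > 0:
        if mask is None:
            raise ValueError("spatial smoothing of the ACF requires a mask")
        from scipy import ndimage
        sd = smooth_fwhm_vox / math.sqrt(8 * math.log(2))
        vol = np.zeros(mask.shape + (T,))
        vol[mask] = acf
        norm = ndimage.gaussian_filter(mask.astype(float), sd)
        for lag in range(1, taper_m):
            sm = ndimage.gaussian_filter(vol[..., lag], sd)
            vol[..., lag] = np.where(mask, sm / np.maximum(norm, 1e-12), 0)
        acf = vol[mask]
        acf[:, 0] = 1.0
    return NoiseModel(method="fsl_tukey", scope="voxelwise", acf=acf,
                      params={"taper_m": taper_m})


# ---------------------------------------------------------------------------
# ReML over covariance components (global models: AR(1)+WN and FAST)


def _reml_components(S: np.ndarray, X: np.ndarray, Qs: list, n_samples: int,
                     maxiter: int = REML_MAXITER, tol: float = REML_TOL):
    """Fisher-scoring ReML for V = sum_j lambda_j Q_j.

    ``S`` is the pooled second-moment matrix of the data (or of the OLS
    residuals — identical restricted likelihood since P X = 0), ``X`` the
    fixed-effects design, ``n_samples`` the number of pooled voxels.
    Returns (lambda, V, n_iter).  Raises on non-convergence, attaching
    the last iterate to the exception.
    """
    T = S.shape[0]
    nq = len(Qs)
    # start from the least-squares projection of S onto the dictionary
    A = np.stack([q.ravel() for q in Qs], axis=1)
    lam, *_ = np.linalg.lstsq(A, S.ravel(), rcond=None)
    V = _lam_to_pd_v(lam, Qs)
    ll_prev = -np.inf
    for it in range(1, maxiter + 1):
        Vi = linalg.inv(V)
        XtViX = X.T @ Vi @ X
        P = Vi - Vi @ X @ linalg.solve(XtViX, X.T @ Vi)
        PS = P @ S
        PQ = [P @ q for q in Qs]
        # tr(A B) = sum(A * B.T): avoids forming the T x T products
        g = np.array([-0.5 * n_samples * (np.trace(pq) - np.sum(pq * PS.T))
                      for pq in PQ])
        H = np.empty((nq, nq))
        for j in range(nq):
            for k in range(j, nq):
                H[j, k] = H[k, j] = 0.5 * n_samples * np.sum(PQ[j] * PQ[k].T)
        # dictionary components are highly collinear: a pseudoinverse step
        # truncates the likelihood-ridge (null-space) directions in which
        # lambda drifts without changing V
        step = np.linalg.pinv(H, rcond=1e-10, hermitian=True) @ g
        # restricted log likelihood (up to constants) for convergence control
        sign, logdet_v = np.linalg.slogdet(V)
        _, logdet_x = np.linalg.slogdet(XtViX)
        ll = -0.5 * (n_samples * logdet_v + logdet_x + n_samples * np.trace(PS))
        # step halving if the update leaves the PD cone or lowers the likelihood
        for half in range(9):
            lam_new = lam + step
            try:
                V_new = _lam_to_pd_v(lam_new, Qs, strict=True)
                break
            except linalg.LinAlgError:
                step = step / 2
        else:
            lam_new, V_new = lam, _lam_to_pd_v(lam, Qs)
        lam, V = lam_new, V_new
        if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
            return lam, V, it
        ll_prev = ll
    err = RuntimeError(f"ReML did not converge within {maxiter} iterations")
    err.last_lambda = lam  # type: ignore[attr-defined]
    err.last_V = V  # type: ignore[attr-defined]
    raise err


def _lam_to_pd_v(lam: np.ndarray, Qs: list, strict: bool = False) -> np.ndarray:
    V = sum(l * q for l, q in zip(lam, Qs))
    try:
        linalg.cholesky(V, lower=True)
        return V
    except linalg.LinAlgError:
        if strict:
            raise
        return _pd_floor(V)


def unwhitened_task_selection(fit: GLMFit, p_threshold: float = 0.001) -> np.ndarray:
    """Voxels with un-pre-whitened task-contrast p below threshold (one-sided).

    This is the voxel subset the global AR(1)+WN estimation pools over;
    falls back to all voxels (logged) when empty or when the design has
    no task column.
    """
    if fit.tmap is None:
        logger.info("no task column: AR(1)+WN selection falls back to all voxels")
        return np.ones(fit.n_voxels, dtype=bool)
    pvals = stats.t.sf(fit.tmap, fit.df)
    sel = pvals < p_threshold
    if not sel.any():
        logger.info("empty p<%.4g selection: falling back to all voxels", p_threshold)
        return np.ones(fit.n_voxels, dtype=bool)
    return sel


def estimate_spm_ar1wn(fit: GLMFit, X: DesignMatrix | None = None,
                       selection: np.ndarray | None = None,
                       ar_coef: float = SPM_AR_COEF) -> NoiseModel:
    """Global AR(1)-plus-white-noise model by two-component ReML.

    The pooled residual second moment over ``selection`` (default: all
    voxels) is fitted as ``V = lambda_1 I + lambda_2 Q(a)`` with the
    AR(1) kernel fixed at ``a = ar_coef`` — the linearized mixture used
    as the default global noise model.
    """
    X = X or fit.design
    R = fit.residuals
    if selection is None:
        selection = np.ones(R.shape[0], dtype=bool)
    selection = np.asarray(selection, dtype=bool)
    if not selection.any():
        logger.info("empty selection passed: falling back to all voxels")
        selection = np.ones(R.shape[0], dtype=bool)
    Rs = R[selection]
    n_sel, T = Rs.shape
    S = (Rs.T @ Rs) / n_sel
    Qs = [np.eye(T), linalg.toeplitz(ar_coef ** np.arange(T))]
    lam, V, n_iter = _reml_components(S, X.matrix, Qs, n_sel)
    acf = V[0] / V[0, 0]
    return NoiseModel(method="spm_ar1wn", scope="global", acf=acf,
                      params={"lambda": lam, "ar_coef": ar_coef,
                              "n_selected": int(n_sel), "n_iter": n_iter})


def fast_dictionary(n_timepoints: int, tr: float, p: int = 6) -> list:
    """Dictionary of 3p exponential covariance components.

    For each of ``p`` time constants tau_j (geometric sequence on
    ``[TR/2, 8 TR]``): the Toeplitz kernel ``exp(-k TR / tau_j)`` together
    with its first and second derivatives with respect to ``1/tau``.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    k = np.arange(n_timepoints) * tr
    taus = np.geomspace(tr / 2.0, 8.0 * tr, p)
    comps = []
    for tau in taus:
        base = np.exp(-k / tau)
        comps.append(linalg.toeplitz(base))
        comps.append(linalg.toeplitz(-k * base))
        comps.append(linalg.toeplitz(k * k * base))
    return comps


def estimate_fast(fit: GLMFit, p: int = 6) -> NoiseModel:
    """Global ReML mixture over the exponential covariance dictionary.

    Mixture weights are unconstrained scalars estimated by Fisher
    scoring on the pooled residual second moment; the resulting V is
    kept positive definite by step halving with an eigenvalue floor.
    """
    R = fit.residuals
    n_vox, T = R.shape
    S = (R.T @ R) / n_vox
    Qs = fast_dictionary(T, fit.design.tr, p)
    lam, V, n_iter = _reml_components(S, fit.design.matrix, Qs, n_vox)
    acf = V[0] / V[0, 0]
    return NoiseModel(method="fast", scope="global", acf=acf,
                      params={"lambda": lam, "p": p,
                              "n_components": len(Qs), "n_iter": n_iter})


def estimate_model(method: str, fit: GLMFit, **kwargs) -> NoiseModel:
    """Dispatch an autocorrelation estimator by method name."""
    if method == "none":
        return identity_model(fit.residuals.shape[1])
    if method == "spm_ar1wn":
        return estimate_spm_ar1wn(fit, **kwargs)
    if method == "afni_arma11":
        return estimate_afni_arma11(fit, **kwargs)
    if method == "fsl_tukey":
        return estimate_fsl_tukey(fit, **kwargs)
    if method == "fast":
        return estimate_fast(fit, **kwargs)
    raise ValueError(f"unknown method {method!r}")
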