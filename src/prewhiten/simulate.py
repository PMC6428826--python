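"""Synthetic BOLD data with known temporal autocorrelation.

Generates the null and task datasets on which the pre-whitening estimators
are evaluated: voxel time series with white, AR(1), ARMA(1,1),
AR(1)-plus-white-noise, or exponential-ACF temporal structure, optional
slow scanner-like drift, optional spatial smoothing, and optional
HRF-convolved task signal from block (boxcar) or event-related designs.

The default grid mirrors a typical resting-state acquisition
(64 x 64 x 33 voxels, T = 225, TR = 2 s).  All generators are
deterministic given their seed; voxels use independent child streams
derived from the master seed and the flat voxel index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .core import VolumeSeries

_NOISE_KINDS = ("white", "ar1", "arma11", "ar1_plus_wn", "exp_acf")
_DESIGN_KINDS = ("boxcar", "event", "none")


@dataclass(frozen=True)
class NoiseSpec:
    """Temporal noise model for one voxel time series.

    Parameters
    ----------
    kind : {'white', 'ar1', 'arma11', 'ar1_plus_wn', 'exp_acf'}
    ar_coef : float
        AR(1) coefficient ``a`` (|a| < 1, stationarity).
    ma_coef : float
        MA(1) coefficient ``b`` for ``arma11`` (|b| < 1).
    wn_fraction : float
        For ``ar1_plus_wn``: fraction of the total variance carried by the
        white component (0..1).
    exp_tau : float
        For ``exp_acf``: time constant in seconds of the exponential
        autocorrelation ``rho(k) = exp(-k*TR/tau)``.
    drift_amplitude : float
        Amplitude (signal units) of the additive low-frequency drift
        (cosine of period 2x run length plus a linear term).
    spatial_fwhm : float
        Gaussian spatial smoothing FWHM in mm applied to the generated
        volume (0 = none).
    sigma : float
        Marginal standard deviation of the noise (signal units).
    """

    kind: str = "ar1"
    ar_coef: float = 0.0
    ma_coef: float = 0.0
    wn_fraction: float = 0.0
    exp_tau: float = 4.0
    drift_amplitude: float = 0.0
    spatial_fwhm: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {_NOISE_KINDS}")
        if abs(self.ar_coef) >= 1:
            raise ValueError(
                f"non-stationary AR coefficient a={self.ar_coef}: stationarity requires |a| < 1"
            )
        if abs(self.ma_coef) >= 1:
            raise ValueError(f"MA coefficient b={self.ma_coef} must satisfy |b| < 1")
        if not 0 <= self.wn_fraction <= 1:
            raise ValueError("wn_fraction must lie in [0, 1]")
        if self.kind == "exp_acf" and not self.exp_tau > 0:
            raise ValueError("exp_tau must be positive (seconds)")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def theoretical_acf(self, nlags: int, tr: float) -> np.ndarray:
        """Closed-form autocorrelation at lags ``0..nlags-1``."""
        k = np.arange(nlags)
        a, b = self.ar_coef, self.ma_coef
        if self.kind == "white":
            rho = np.zeros(nlags)
            rho[0] = 1.0
        elif self.kind == "ar1":
            rho = a ** k.astype(float)
        elif self.kind == "arma11":
            rho = np.empty(nlags)
            rho[0] = 1.0
            if nlags > 1:
                rho[1] = (1 + a * b) * (a + b) / (1 + 2 * a * b + b * b)
                for i in range(2, nlags):
                    rho[i] = a * rho[i - 1]
        elif self.kind == "ar1_plus_wn":
            rho = (1 - self.wn_fraction) * a ** k.astype(float)
            rho[0] = 1.0
        else:  # exp_acf
            rho = np.exp(-k * tr / self.exp_tau)
        return rho

    def burn_in(self, tr: float) -> int:
        """Samples to discard: 10x the dominant time constant, min 10."""
        tc = 1.0
        if self.kind in ("ar1", "arma11", "ar1_plus_wn"):
            tc = 1.0 / (1.0 - abs(self.ar_coef))
        elif self.kind == "exp_acf":
            tc = self.exp_tau / tr
        return max(10, int(math.ceil(10 * tc)))


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design description.

    ``boxcar``: alternating rest/stimulus blocks (``off_s`` s rest then
    ``on_s`` s stimulus, starting with rest).  ``event``: events of
    ``event_duration_s`` separated by ISIs drawn uniformly from
    ``[isi_low_s, isi_high_s]``.  ``none``: resting state.
    """

    kind: str = "boxcar"
    off_s: float = 10.0
    on_s: float = 10.0
    isi_low_s: float = 3.0
    isi_high_s: float = 6.0
    event_duration_s: float = 0.1
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _DESIGN_KINDS:
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.kind == "boxcar" and not (self.off_s > 0 and self.on_s > 0):
            raise ValueError("boxcar requires off_s, on_s > 0")
        if self.kind == "event":
            if self.isi_low_s > self.isi_high_s:
                raise ValueError("event requires isi_low_s <= isi_high_s")
            if self.event_duration_s < 0:
                raise ValueError("event_duration_s must be >= 0")
        if not self.label:
            if self.kind == "boxcar":
                object.__setattr__(self, "label", f"boxcar{self.off_s:g}")
            else:
                object.__setattr__(self, "label", self.kind)

    @property
    def period_s(self) -> float:
        """Fundamental period of a boxcar design (off + on), seconds."""
        if self.kind != "boxcar":
            raise ValueError("period_s is defined for boxcar designs only")
        return self.off_s + self.on_s

    @property
    def fundamental_frequency_hz(self) -> float:
        return 1.0 / self.period_s


def boxcar(half_period_s: float) -> DesignSpec:
    """'boxcarK' convention: K s rest followed by K s stimulus."""
    return DesignSpec(kind="boxcar", off_s=half_period_s, on_s=half_period_s,
                      label=f"boxcar{half_period_s:g}")


@dataclass(frozen=True)
class GridSpec:
    """Acquisition geometry: grid, run length, TR and voxel size (mm)."""

    nx: int = 64
    ny: int = 64
    nz: int = 33
    n_timepoints: int = 225
    tr: float = 2.0
    voxel_size: tuple = (3.1, 3.1, 3.6)

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz, self.n_timepoints) < 1:
            raise ValueError("grid dimensions and T must be positive")
        if not self.tr > 0:
            raise ValueError("TR must be positive")
        if len(self.voxel_size) != 3 or min(self.voxel_size) <= 0:
            raise ValueError("voxel_size must be a positive mm triple")

    @property
    def shape(self) -> tuple:
        return (self.nx, self.ny, self.nz)

    @property
    def duration_s(self) -> float:
        return self.n_timepoints * self.tr


@dataclass
class StimulusTimeline:
    """Realized stimulus onsets/durations (seconds) within a run."""

    onsets: np.ndarray
    durations: np.ndarray
    total_duration: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.onsets.shape != self.durations.shape:
            raise ValueError("onsets and durations must have equal length")
        if self.onsets.size:
            if np.any(np.diff(self.onsets) < 0):
                raise ValueError("onsets must be sorted")
            if self.onsets[0] < 0 or self.onsets[-1] > self.total_duration:
                raise ValueError("onsets must lie within [0, total_duration]")
        if not self.total_duration > 0:
            raise ValueError("total_duration must be positive")

    def to_file(self, path) -> None:
        """Write as FSL-style 3-column text (onset, duration, amplitude)."""
        arr = np.column_stack([self.onsets, self.durations, np.ones_like(self.onsets)])
        np.savetxt(path, arr, fmt="%.6g", delimiter="\t")

    @classmethod
    def from_file(cls, path, total_duration: float) -> "StimulusTimeline":
        arr = np.atleast_2d(np.loadtxt(path))
        if arr.size == 0:
            return cls(np.empty(0), np.empty(0), total_duration)
        return cls(arr[:, 0], arr[:, 1], total_duration)


def _innovation_scale(spec: NoiseSpec) -> float:
    """Innovation sd giving the filtered series unit marginal variance."""
    a, b = spec.ar_coef, spec.ma_coef
    if spec.kind == "white":
        return 1.0
    if spec.kind in ("ar1", "ar1_plus_wn"):
        return math.sqrt(1.0 - a * a)
    if spec.kind == "arma11":
        return math.sqrt((1.0 - a * a) / (1.0 + 2 * a * b + b * b))
    raise AssertionError(spec.kind)


def _filter_noise(spec: NoiseSpec, innovations: np.ndarray, tr: float) -> np.ndarray:
    """Apply the ARMA recursion along the last axis; output has unit variance."""
    a, b = spec.ar_coef, spec.ma_coef
    if spec.kind == "exp_acf":
        # exponential ACF == AR(1) with coefficient exp(-TR/tau)
        a = math.exp(-tr / spec.exp_tau)
        x = signal.lfilter([1.0], [1.0, -a], innovations, axis=-1)
        return x * math.sqrt(1.0 - a * a)
    if spec.kind == "white":
        return innovations
    if spec.kind == "ar1":
        x = signal.lfilter([1.0], [1.0, -a], innovations, axis=-1)
        return x * _innovation_scale(spec)
    if spec.kind == "arma11":
        x = signal.lfilter([1.0, b], [1.0, -a], innovations, axis=-1)
        return x * _innovation_scale(spec)
    raise AssertionError(spec.kind)


def gen_noise_timeseries(spec: NoiseSpec, n_timepoints: int, tr: float,
                         seed) -> np.ndarray:
    """Generate one zero-mean stationary noise series of length T.

    The series has marginal variance ``spec.sigma**2`` and the
    closed-form autocorrelation of the requested family.  A burn-in of at
    least 10x the dominant time constant is generated and discarded so
    the initialization transient is gone.  Deterministic given ``seed``
    (an int or a ``numpy.random.Generator``/``SeedSequence``).
    """
    if n_timepoints < 10:
        raise ValueError("n_timepoints must be >= 10")
    rng = np.random.default_rng(seed)
    burn = spec.burn_in(tr)
    if spec.kind == "ar1_plus_wn":
        e = rng.standard_normal(n_timepoints + burn)
        w = rng.standard_normal(n_timepoints + burn)
        ar = _filter_noise(
            NoiseSpec(kind="ar1", ar_coef=spec.ar_coef), e, tr)
        x = math.sqrt(1 - spec.wn_fraction) * ar + math.sqrt(spec.wn_fraction) * w
    else:
        e = rng.standard_normal(n_timepoints + burn)
        x = _filter_noise(spec, e, tr)
    return spec.sigma * x[burn:]


def gen_design_timeline(spec: DesignSpec, total_duration: float,
                        seed=0) -> StimulusTimeline:
    """Realize a design as a stimulus timeline over ``total_duration`` s.

    Boxcar designs alternate off/on blocks starting with off; event
    designs accumulate uniform ISIs from the run start.  Deterministic
    given ``seed`` (only event designs consume randomness).
    """
    if not total_duration > 0:
        raise ValueError("total_duration must be positive")
    if spec.kind == "none":
        return StimulusTimeline(np.empty(0), np.empty(0), total_duration)
    if spec.kind == "boxcar":
        if total_duration < spec.period_s:
            raise ValueError("total_duration shorter than one design period")
        onsets, durations = [], []
        t = spec.off_s
        while t < total_duration:
            onsets.append(t)
            durations.append(min(spec.on_s, total_duration - t))
            t += spec.period_s
        return StimulusTimeline(np.array(onsets), np.array(durations), total_duration)
    # event-related
    if total_duration < spec.isi_high_s:
        raise ValueError("total_duration shorter than the maximum ISI")
    rng = np.random.default_rng(seed)
    onsets = []
    t = float(rng.uniform(spec.isi_low_s, spec.isi_high_s))
    while t + spec.event_duration_s <= total_duration:
        onsets.append(t)
        t += float(rng.uniform(spec.isi_low_s, spec.isi_high_s))
    onsets = np.array(onsets)
    return StimulusTimeline(onsets, np.full(onsets.shape, spec.event_duration_s),
                            total_duration)


def _voxel_streams(master_seed: int, n_voxels: int):
    """Independent per-voxel bit streams: master seed + flat voxel index."""
    root = np.random.SeedSequence(master_seed)
    return root.spawn(n_voxels)


def _drift(n_timepoints: int, tr: float, amplitude: float,
           rng: np.random.Generator) -> np.ndarray:
    """Slow cosine (period 2x run length) plus linear trend, random phase sign."""
    t = np.arange(n_timepoints) * tr
    dur = n_timepoints * tr
    cos = np.cos(np.pi * t / dur)
    lin = np.linspace(-1, 1, n_timepoints)
    s1, s2 = rng.choice([-1.0, 1.0], size=2)
    return amplitude * (s1 * cos + 0.5 * s2 * lin)


def ellipsoid_mask(grid: GridSpec, radius_frac: float = 0.9) -> np.ndarray:
    """Axis-aligned ellipsoid mask centered in the grid."""
    ax = [(np.arange(n) - (n - 1) / 2) / (radius_frac * n / 2)
          for n in (grid.nx, grid.ny, grid.nz)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    return xx**2 + yy**2 + zz**2 <= 1.0


def gen_resting_volume(grid: GridSpec, noise: NoiseSpec, seed: int,
                       mask: np.ndarray | None = None) -> VolumeSeries:
    """Generate a resting (null) 4D dataset.

    Every in-mask voxel time series is drawn independently per
    ``noise``; optional Gaussian spatial smoothing (``noise.spatial_fwhm``
    mm, applied volume-wise and variance-renormalized) and additive
    low-frequency drift follow.  Deterministic given ``seed``.
    """
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape must match grid")
    n_vox = int(mask.sum())
    t_len = grid.n_timepoints
    burn = noise.burn_in(grid.tr)

    streams = _voxel_streams(seed, n_vox + 1)
    aux_rng = np.random.default_rng(streams[0])  # drift phase etc.

    if noise.sigma == 0:
        flat = np.zeros((n_vox, t_len))
    else:
        innov = np.empty((n_vox, t_len + burn))
        extra = np.empty((n_vox, t_len + burn)) if noise.kind == "ar1_plus_wn" else None
        for i, ss in enumerate(streams[1:]):
            rng = np.random.default_rng(ss)
            innov[i] = rng.standard_normal(t_len + burn)
            if extra is not None:
                extra[i] = rng.standard_normal(t_len + burn)
        if noise.kind == "ar1_plus_wn":
            ar = _filter_noise(NoiseSpec(kind="ar1", ar_coef=noise.ar_coef),
                               innov, grid.tr)
            flat = (math.sqrt(1 - noise.wn_fraction) * ar
                    + math.sqrt(noise.wn_fraction) * extra)
        else:
            flat = _filter_noise(noise, innov, grid.tr)
        flat = noise.sigma * flat[:, burn:]

    data = np.zeros(grid.shape + (t_len,), dtype=np.float64)
    data[mask] = flat

    if noise.spatial_fwhm > 0 and noise.sigma > 0:
        sd_vox = [noise.spatial_fwhm / math.sqrt(8 * math.log(2)) / vs
                  for vs in grid.voxel_size]
        before = data[mask].std()
        data = ndimage.gaussian_filter(data, sigma=sd_vox + [0.0])
        after = data[mask].std()
        if after > 0:
            data *= before / after  # keep the marginal variance at sigma^2
        data[~mask] = 0.0

    if noise.drift_amplitude > 0:
        data[mask] += _drift(t_len, grid.tr, noise.drift_amplitude, aux_rng)

    return VolumeSeries(data=data, tr=grid.tr, mask=mask)


def hrf_regressor(timeline: StimulusTimeline, n_timepoints: int, tr: float) -> np.ndarray:
    """HRF-convolved, peak-normalized task regressor on the TR grid."""
    from .design import canonical_hrf, convolve_timeline

    dt = min(tr / 16.0, 0.1)
    reg = convolve_timeline(timeline, canonical_hrf(dt), n_timepoints, tr)
    peak = np.max(np.abs(reg))
    return reg / peak if peak > 0 else reg


def gen_task_volume(grid: GridSpec, noise: NoiseSpec, timeline: StimulusTimeline,
                    effect_size: float, active_region: np.ndarray, seed: int,
                    mask: np.ndarray | None = None) -> VolumeSeries:
    """Resting volume plus HRF-convolved task signal in ``active_region``.

    ``effect_size`` is percent signal change against the nominal 100-unit
    baseline of BOLD data, i.e. the peak-normalized task regressor is
    scaled to an amplitude of ``effect_size`` image units (noise sigma is
    in the same units).  ``effect_size=0`` reproduces
    :func:`gen_resting_volume` bit for bit at the same seed.
    """
    vol = gen_resting_volume(grid, noise, seed, mask=mask)
    if effect_size == 0:
        return vol
    active_region = np.asarray(active_region, dtype=bool)
    if not active_region.any():
        raise ValueError("active_region is empty but effect_size > 0")
    if np.any(active_region & ~vol.mask):
        raise ValueError("active_region must be a subset of the mask")
    sig = effect_size * hrf_regressor(timeline, grid.n_timepoints, grid.tr)
    vol.data[active_region] += sig
    return vol
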