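"""Hemodynamic response modeling and design-matrix construction.

The canonical double-gamma HRF (response peak 5 s after onset,
post-stimulus undershoot around 15 s, undershoot ratio 1/6) and its
temporal derivative are convolved with a stimulus timeline on a
sub-TR microtime grid, downsampled to the TR grid, and combined with
optional motion confounds and a discrete-cosine high-pass basis
(default cutoff 1/100 Hz) into a full-rank design matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GridSpec, StimulusTimeline

#: gamma shape/scale of the response and undershoot components and the
#: undershoot ratio; chosen so the peak sits at 5.00 s and the
#: post-peak minimum at 15.1 s on a 0.01 s grid.
HRF_RESPONSE_SHAPE = 6.0
HRF_RESPONSE_SCALE = 1.0
HRF_UNDERSHOOT_SHAPE = 15.0
HRF_UNDERSHOOT_SCALE = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_LENGTH_S = 32.0

COLUMN_ROLES = ("task", "temporal_derivative", "motion", "dct", "intercept")


@dataclass
class HRFKernel:
    """Sampled HRF-like kernel on a microtime grid of step ``dt`` s."""

    dt: float
    values: np.ndarray
    length: float = HRF_LENGTH_S

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    def peak_time(self) -> float:
        return float(self.times[np.argmax(self.values)])


@dataclass
class DesignMatrix:
    """T x K regressor matrix with per-column roles.

    ``column_roles`` uses 'dct' for the cosine drift columns, with the
    constant column labelled 'intercept'.  The task contrast used
    throughout the package is the unit vector on the 'task' column.
    """

    matrix: np.ndarray
    column_roles: list
    tr: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.column_roles):
            raise ValueError("matrix columns must match column_roles")
        bad = set(self.column_roles) - set(COLUMN_ROLES)
        if bad:
            raise ValueError(f"unknown column roles: {sorted(bad)}")
        if self.column_roles.count("intercept") != 1:
            raise ValueError("design must contain exactly one intercept")
        r = self.rank
        if r < self.matrix.shape[1]:
            raise ValueError(self._collinearity_message(r))

    def _collinearity_message(self, rank: int) -> str:
        # name the roles whose removal restores full rank
        culprits = []
        for j, role in enumerate(self.column_roles):
            reduced = np.delete(self.matrix, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                culprits.append(role)
        return (f"design matrix is rank deficient (rank {rank} < "
                f"{self.matrix.shape[1]} columns); collinear roles: "
                f"{sorted(set(culprits))}")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    @property
    def task_contrast(self) -> np.ndarray | None:
        """Unit contrast vector on the task column, or None for rest designs."""
        if "task" not in self.column_roles:
            return None
        c = np.zeros(self.n_columns)
        c[self.column_roles.index("task")] = 1.0
        return c

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=self.column_roles).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tr: float) -> "DesignMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(), list(df.columns), tr)


def canonical_hrf(dt: float) -> HRFKernel:
    """Canonical double-gamma HRF sampled on ``[0, 32]`` s at step ``dt``.

    Response gamma (shape 6, scale 1) minus the undershoot gamma
    (shape 15, scale 1) scaled by 1/6; normalized to peak amplitude 1;
    ``h(0) = 0``.
    """
    if not 0 < dt <= 0.5:
        raise ValueError("dt must lie in (0, 0.5] seconds")
    t = np.arange(0, HRF_LENGTH_S + dt / 2, dt)
    h = (stats.gamma.pdf(t, HRF_RESPONSE_SHAPE, scale=HRF_RESPONSE_SCALE)
         - stats.gamma.pdf(t, HRF_UNDERSHOOT_SHAPE, scale=HRF_UNDERSHOOT_SCALE)
         * HRF_UNDERSHOOT_RATIO)
    h /= h.max()
    return HRFKernel(dt=dt, values=h)


def temporal_derivative(hrf: HRFKernel) -> HRFKernel:
    """First finite-difference derivative of the HRF on its own grid."""
    d = np.gradient(hrf.values, hrf.dt)
    return HRFKernel(dt=hrf.dt, values=d, length=hrf.length)


def dct_highpass_basis(n_timepoints: int, tr: float,
                       cutoff_period: float = 100.0) -> np.ndarray:
    """Orthonormal DCT drift basis including the constant column.

    The number of columns is ``k = floor(2 * T * TR / cutoff_period + 1)``
    so the basis spans all cosines of period longer than ``cutoff_period``
    seconds (default 100 s, i.e. a 1/100 Hz high-pass).
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    if not cutoff_period > 2 * tr:
        raise ValueError("cutoff_period must exceed 2*TR")
    duration = n_timepoints * tr
    k = int(math.floor(2.0 * duration / cutoff_period + 1.0))
    if k > n_timepoints:
        raise ValueError(
            f"cutoff_period {cutoff_period}s yields {k} columns > T={n_timepoints}")
    n = np.arange(n_timepoints)
    basis = np.empty((n_timepoints, k))
    basis[:, 0] = 1.0 / math.sqrt(n_timepoints)
    for j in range(1, k):
        basis[:, j] = math.sqrt(2.0 / n_timepoints) * np.cos(
            math.pi * j * (2 * n + 1) / (2.0 * n_timepoints))
    return basis


def convolve_timeline(timeline: StimulusTimeline, hrf: HRFKernel,
                      n_timepoints: int, tr: float) -> np.ndarray:
    """Microtime convolution of a timeline with a kernel, on the TR grid.

    The stimulus indicator is rasterized on the kernel's dt grid
    (events shorter than one microtime step still occupy one bin),
    convolved, scaled by dt so the output approximates the continuous
    convolution integral, and sampled at acquisition times ``i*TR``.
    """
    dt = hrf.dt
    n_micro = int(round(n_timepoints * tr / dt))
    stim = np.zeros(n_micro)
    for onset, dur in zip(timeline.onsets, timeline.durations):
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + dur) / dt)))
        stim[i0:min(i1, n_micro)] = 1.0
    conv = np.convolve(stim, hrf.values)[:n_micro] * dt
    step = tr / dt
    idx = np.round(np.arange(n_timepoints) * step).astype(int)
    return conv[idx]


def build_design_matrix(timeline: StimulusTimeline | None, grid: GridSpec,
                        motion: np.ndarray | None = None,
                        cutoff_period: float = 100.0) -> DesignMatrix:
    """Assemble the GLM design matrix.

    Columns, in order: task regressor (HRF-convolved timeline) and its
    temporal-derivative regressor (omitted for rest), six motion
    confounds if given, and the DCT high-pass basis with its constant
    column as the intercept.  Microtime resolution is TR/16, capped at
    0.1 s when the timeline contains sub-TR events.
    """
    t_len, tr = grid.n_timepoints, grid.tr
    cols, roles = [], []
    if timeline is not None and timeline.onsets.size:
        if abs(timeline.total_duration - t_len * tr) > tr:
            raise ValueError("timeline duration must match T*TR")
        dt = tr / 16.0
        if np.any(timeline.durations < tr):
            dt = min(dt, 0.1)
        hrf = canonical_hrf(dt)
        cols.append(convolve_timeline(timeline, hrf, t_len, tr))
        roles.append("task")
        cols.append(convolve_timeline(timeline, temporal_derivative(hrf), t_len, tr))
        roles.append("temporal_derivative")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != t_len:
            raise ValueError("motion confounds must have T rows")
        for j in range(motion.shape[1]):
            cols.append(motion[:, j])
            roles.append("motion")
    dct = dct_highpass_basis(t_len, tr, cutoff_period)
    cols.append(dct[:, 0])
    roles.append("intercept")
    for j in range(1, dct.shape[1]):
        cols.append(dct[:, j])
        roles.append("dct")
    return DesignMatrix(np.column_stack(cols), roles, tr)
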