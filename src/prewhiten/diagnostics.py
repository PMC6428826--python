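"""Whitening diagnostics: normalized power spectra of GLM residuals.

Statistical inference after pre-whitening assumes the residuals are
white; white residuals have a flat power spectrum.  Each residual
series is demeaned, scaled to sample variance 1 (so different signal
scaling across voxels and subjects cannot distort averages), and its
periodogram taken at the positive DFT frequencies up to Nyquist
(0.5/TR).  The normalization makes the spectrum of white noise equal
1 at every frequency and the mean over frequencies exactly 1
(Parseval), so departures from 1 read directly as residual
autocorrelation structure.  Spectra are averaged across voxels within
subject and then across subjects, and summarized by per-band means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PowerSpectrum:
    """Variance-normalized residual power spectrum.

    ``frequencies`` are the positive DFT frequencies (Hz), strictly
    increasing up to the Nyquist frequency 0.5/TR; DC is excluded
    because series are demeaned.  ``power`` is scaled so white noise
    has expectation 1 and a single series averages exactly 1 across
    frequencies.  ``n_pooled`` counts the voxel series pooled in.
    """

    frequencies: np.ndarray
    power: np.ndarray
    n_pooled: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have equal shape")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def nyquist_hz(self) -> float:
        return float(self.frequencies[-1])

    def to_tsv(self, path) -> None:
        pd.DataFrame({"frequency_hz": self.frequencies, "power": self.power,
                      "n_pooled": self.n_pooled}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PowerSpectrum":
        df = pd.read_csv(path, sep="\t")
        return cls(df["frequency_hz"].to_numpy(), df["power"].to_numpy(),
                   int(df["n_pooled"].iloc[0]))


def residual_power_spectrum(residual_series: np.ndarray, tr: float) -> PowerSpectrum:
    """Normalized periodogram of one series or the pooled mean of many rows.

    ``residual_series`` may be 1D (one voxel) or 2D ``(n_voxels, T)``,
    in which case voxel spectra are averaged (equal weight per voxel).
    Zero-variance rows raise, naming the offending voxel.
    """
    X = np.atleast_2d(np.asarray(residual_series, dtype=float))
    n_vox, T = X.shape
    if T < 8:
        raise ValueError("need at least 8 time points")
    X = X - X.mean(axis=1, keepdims=True)
    var = np.einsum("vt,vt->v", X, X) / T
    bad = np.where(var <= 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance residual series at voxel index {bad[0]}")
    X = X / np.sqrt(var)[:, None]
    m = T // 2
    F = np.fft.rfft(X, axis=1)[:, 1:m + 1]
    weights = np.full(m, 2.0)
    if T % 2 == 0:
        weights[-1] = 1.0  # Nyquist bin has no conjugate pair
    power = (np.abs(F) ** 2 * weights) * (m / T**2)
    freqs = np.arange(1, m + 1) / (T * tr)
    return PowerSpectrum(freqs, power.mean(axis=0), n_pooled=n_vox)


def pool_spectra(spectra: list) -> PowerSpectrum:
    """Pointwise mean of spectra on identical frequency grids.

    Averaging is equal-weight per input spectrum (voxels within a
    subject are already pooled by :func:`residual_power_spectrum`, so
    passing per-subject spectra weights subjects equally).
    """
    if not spectra:
        raise ValueError("no spectra to pool")
    f0 = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != f0.shape or not np.allclose(s.frequencies, f0):
            raise ValueError("mismatched frequency grids; no interpolation is done")
    power = np.mean([s.power for s in spectra], axis=0)
    return PowerSpectrum(f0, power, n_pooled=sum(s.n_pooled for s in spectra))


def flatness_metrics(spectrum: PowerSpectrum,
                     band_edges: np.ndarray | None = None,
                     f_min: float = 0.0) -> dict:
    """Scalar whitening summary: per-band means and low-frequency excess.

    ``band_edges`` are interior edges in Hz splitting ``(f_min, Nyquist]``
    into bands; by default the quartile edges of that interval.  Set
    ``f_min`` to the high-pass cutoff (e.g. 0.01 Hz for a 1/100 Hz
    filter) to evaluate flatness over the passband only — below the
    cutoff the drift regressors null the residual spectrum by
    construction, so whitening quality is unmeasurable there.  Returns
    ``band_means``, ``band_edges_hz`` and ``low_excess`` (lowest-band
    mean minus 1, the signature of residual positive autocorrelation).
    """
    f, p = spectrum.frequencies, spectrum.power
    nyq = spectrum.nyquist_hz
    if not 0 <= f_min < nyq:
        raise ValueError("f_min must lie in [0, Nyquist)")
    if band_edges is None:
        band_edges = f_min + (nyq - f_min) * np.array([0.25, 0.5, 0.75])
    edges = np.concatenate([[f_min], np.asarray(band_edges, dtype=float), [nyq]])
    if np.any(np.diff(edges) <= 0) or edges[-2] >= nyq or edges[1] <= f_min:
        raise ValueError("band edges must be increasing and inside (f_min, Nyquist)")
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (f > lo) & (f <= hi)
        if not sel.any():
            raise ValueError(f"empty frequency band ({lo:g}, {hi:g}] Hz")
        means.append(float(p[sel].mean()))
    return {"band_means": np.array(means),
            "band_edges_hz": edges,
            "low_excess": means[0] - 1.0}


def plot_spectra(spectra: dict, path, title: str = "") -> None:
    """Diagnostic plot: residual power vs. frequency, one line per method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.2))
    for label, spec in spectra.items():
        ax.plot(spec.frequencies, spec.power, label=label, lw=1.2)
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("frequency [Hz]")
    ax.set_ylabel("normalized power of GLM residuals")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
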