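import math

import numpy as np
import pytest
from scipy import ndimage

import prewhiten as pw


@pytest.fixture(scope="session")
def small_grid():
    """5200-voxel grid at the reference run length (T=225, TR=2 s)."""
    return pw.GridSpec(nx=20, ny=26, nz=10, n_timepoints=225, tr=2.0)


@pytest.fixture(scope="session")
def boxcar10_design(small_grid):
    timeline = pw.gen_design_timeline(pw.boxcar(10), small_grid.duration_s)
    return pw.build_design_matrix(timeline, small_grid)


@pytest.fixture(scope="session")
def rest_design(small_grid):
    """Intercept-only design: no high-pass distortion of the noise ACF."""
    return pw.build_design_matrix(None, small_grid, cutoff_period=1e12)


def smooth_null_field(rng, shape, fwhm_vox):
    """Stationary unit-variance Gaussian field with Gaussian ACF.

    White noise is generated on a padded grid, smoothed with a Gaussian
    kernel of the requested FWHM (voxels), cropped, and normalized by the
    exact discrete kernel norm, so edge voxels have the same marginal
    variance as the interior (reflect-style boundaries would inflate the
    excursion probability at the borders).
    """
    sd = fwhm_vox / math.sqrt(8 * math.log(2))
    pad = int(math.ceil(4 * sd))
    big = rng.standard_normal(tuple(s + 2 * pad for s in shape))
    sm = ndimage.gaussian_filter(big, sd, mode="constant")
    sm = sm[tuple(slice(pad, pad + s) for s in shape)]
    delta = np.zeros((2 * pad + 1,) * 3)
    delta[pad, pad, pad] = 1.0
    norm = math.sqrt((ndimage.gaussian_filter(delta, sd, mode="constant") ** 2).sum())
    return sm / norm
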