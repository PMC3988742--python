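"""Windowed (ball-neighborhood) region statistics.

The localized active contour needs, at every narrowband point x, the mean and
variance of the image over interior-and-window and exterior-and-window, where
the window is the Euclidean ball of the point's own (possibly adaptive)
radius.  Radii are quantized to integer voxels; for each distinct radius the
per-voxel windowed sums are obtained by FFT convolution with the ball
indicator, and the exterior sums are derived from cached whole-image
convolutions minus the interior ones, so each iteration costs a handful of
FFTs per distinct radius.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

_KERNELS: dict = {}


def ball_kernel(radius: int, ndim: int) -> np.ndarray:
    """Binary indicator of the ball {y : ||y|| <= radius} on the voxel grid."""
    radius = int(radius)
    key = (radius, ndim)
    if key not in _KERNELS:
        ax = np.arange(-radius, radius + 1, dtype=float)
        grids = np.meshgrid(*([ax] * ndim), indexing="ij")
        d2 = sum(g * g for g in grids)
        _KERNELS[key] = (d2 <= radius * radius + 1e-9).astype(float)
    return _KERNELS[key]


def _conv(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = fftconvolve(field, kernel, mode="same")
    # FFT round-off can make exact zeros slightly negative
    return out


class LocalStatsEngine:
    """Caches image-dependent convolutions for one (static) image.

    For a given integer radius r and interior indicator M, supplies at every
    voxel the windowed counts/sums needed for the two-sided Gaussian MLE:
    n_in, S_in, Q_in (count, sum I, sum I^2 over interior ∩ ball) and the
    same for the exterior, obtained from the static whole-window sums.
    """

    def __init__(self, image: np.ndarray):
        self.image = np.asarray(image, dtype=float)
        self._static: dict = {}  # radius -> (n_all, S_all, Q_all)

    def _static_sums(self, radius: int):
        radius = int(radius)
        if radius not in self._static:
            k = ball_kernel(radius, self.image.ndim)
            ones = np.ones_like(self.image)
            n_all = _conv(ones, k)
            S_all = _conv(self.image, k)
            Q_all = _conv(self.image * self.image, k)
            self._static[radius] = (n_all, S_all, Q_all)
        return self._static[radius]

    def side_sums(self, inside: np.ndarray, radius: int):
        """(n_in, S_in, Q_in, n_out, S_out, Q_out) arrays for one radius."""
        k = ball_kernel(int(radius), self.image.ndim)
        m = inside.astype(float)
        n_in = _conv(m, k)
        S_in = _conv(m * self.image, k)
        Q_in = _conv(m * self.image * self.image, k)
        n_all, S_all, Q_all = self._static_sums(int(radius))
        return n_in, S_in, Q_in, n_all - n_in, S_all - S_in, Q_all - Q_in

    def windowed_mean(self, field: np.ndarray, support: np.ndarray, radius: int):
        """Mean of ``field`` over support ∩ ball, per voxel (NaN where empty)."""
        k = ball_kernel(int(radius), self.image.ndim)
        m = support.astype(float)
        n = _conv(m, k)
        s = _conv(m * np.nan_to_num(field), k)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = s / n
        out[n < 0.5] = np.nan
        return out


def side_stats_multiradius(
    engine: LocalStatsEngine,
    inside: np.ndarray,
    radii: np.ndarray,
    points: np.ndarray,
    sigma2_floor: float,
    shrink_n: float = 25.0,
    shrink_var: float = None,
):
    """Two-sided windowed Gaussian statistics at each ``points`` voxel.

    ``radii`` is an integer voxel radius map (only values at ``points`` are
    used).  Returns dict with mu1, var1, n1, mu2, var2, n2 full-grid arrays
    (valid on ``points``).  Where one side is empty in the window, that
    side's stats fall back to the global statistics of that side; variances
    are floored at ``sigma2_floor``.

    Windowed variances are shrunk with pseudo-count ``shrink_n`` toward
    ``shrink_var`` when given (typically the image noise variance), else
    toward the side's global variance: a window holding only a handful of
    voxels of one side gives a wildly unstable variance MLE, and the
    resulting likelihood ratios would pin the contour at noise dips.  A
    noise-level target preserves locality on images with slow intensity
    trends (a global variance would be inflated by the trend).  Pass
    ``shrink_n=0`` for the raw MLE.
    """
    image = engine.image
    shape = image.shape
    mu1 = np.zeros(shape)
    var1 = np.full(shape, sigma2_floor)
    n1 = np.zeros(shape)
    mu2 = np.zeros(shape)
    var2 = np.full(shape, sigma2_floor)
    n2 = np.zeros(shape)

    ins = inside.astype(bool)
    out = ~ins
    glob = {}
    for name, m in (("in", ins), ("out", out)):
        if m.any():
            v = image[m]
            glob[name] = (float(v.mean()), max(float(v.var()), sigma2_floor))
        else:
            glob[name] = (float(image.mean()), sigma2_floor)

    for r in np.unique(radii[points]):
        sel = points & (radii == r)
        if not sel.any():
            continue
        ni, Si, Qi, no, So, Qo = engine.side_sums(ins, int(r))
        for (n_arr, S, Q, mu_t, var_t, n_t, gname) in (
            (ni, Si, Qi, mu1, var1, n1, "in"),
            (no, So, Qo, mu2, var2, n2, "out"),
        ):
            n_here = np.maximum(n_arr[sel], 0.0)
            ok = n_here > 0.5
            with np.errstate(invalid="ignore", divide="ignore"):
                m_here = S[sel] / n_here
                v_here = Q[sel] / n_here - m_here * m_here
            gmu, gvar = glob[gname]
            target = gvar if shrink_var is None else float(shrink_var)
            m_here = np.where(ok, m_here, gmu)
            v_here = np.where(ok, v_here, 0.0)
            if shrink_n > 0:
                v_here = (n_here * np.maximum(v_here, 0.0) + shrink_n * target) / (
                    n_here + shrink_n
                )
            else:
                v_here = np.where(ok, v_here, gvar)
            mu_t[sel] = m_here
            var_t[sel] = np.maximum(v_here, sigma2_floor)
            n_t[sel] = n_here
    return {"mu1": mu1, "var1": var1, "n1": n1, "mu2": mu2, "var2": var2, "n2": n2}
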