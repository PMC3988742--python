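"""Global histogram mixture and the adaptive localization scale.

A contrast-enhanced CT angiogram's global histogram has a few broad Gaussian
modes (air, soft tissue, contrast-filled blood pool).  We fit a K-component
Gaussian mixture by EM, designate the brightest component as the blood pool,
and use the Bhattacharyya distance between the contour's local interior
statistics and the blood-pool Gaussian to pick a per-point localization
radius: interiors that look like blood get a large window (robust to noise),
interiors that deviate (weak local contrast) get a small one (sensitive to
faint edges):

    r(x) = min_scale + max_scale * exp(-tau * D_B(x))

with the closed-form Gaussian Bhattacharyya distance

    D_B = 1/4 ln(1/4 (s1/sb + sb/s1 + 2)) + 1/4 (mu1-mub)^2 / (s1+sb),

s denoting variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .grid import as_image
from .localize import LocalStatsEngine, side_stats_multiradius


@dataclass
class BloodPoolModel:
    """A fitted 1D Gaussian mixture plus the index of the blood-pool mode."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    blood_index: int
    converged: bool = True
    loglik_trace: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.variances <= 0).any():
            raise ValueError("mixture variances must be positive")
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        if not 0 <= self.blood_index < len(self.means):
            raise ValueError("blood_index out of range")

    @property
    def blood_mean(self) -> float:
        return float(self.means[self.blood_index])

    @property
    def blood_variance(self) -> float:
        return float(self.variances[self.blood_index])


@dataclass(frozen=True)
class ScaleParams:
    """Bounds and decay rate of the adaptive window radius (voxels).

    The radius lives in [min_scale, min_scale + max_scale]; tau sets how fast
    it shrinks as the local statistics drift away from the blood pool.
    """

    min_scale: float = 4.0
    max_scale: float = 10.0
    tau: float = 1.0

    def __post_init__(self):
        if self.min_scale < 1:
            raise ValueError("min_scale must be >= 1 voxel")
        if self.max_scale < 0:
            raise ValueError("max_scale must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    @property
    def r_max(self) -> float:
        return self.min_scale + self.max_scale


class DegenerateMixtureError(RuntimeError):
    """EM collapsed a component onto (near-)zero variance."""


def fit_histogram_gmm(
    image,
    n_components: int = 3,
    seed: int = 0,
    max_voxels: int = 200_000,
    blood_index: int = None,
    track_loglik: bool = False,
    max_iter: int = 200,
) -> BloodPoolModel:
    """Fit the global intensity histogram with a K-Gaussian mixture by EM.

    Intensities are subsampled to at most ``max_voxels`` values (seeded) for
    speed.  The blood-pool component defaults to the one with the largest
    mean (contrast-enhanced blood is the brightest tissue class); pass
    ``blood_index`` to override.  With ``track_loglik=True`` EM is stepped
    one iteration at a time and the per-iteration mean log-likelihood trace
    is stored on the model (it is nondecreasing, a standard EM guarantee).
    """
    img = as_image(image)
    x = img.data.reshape(-1)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if np.unique(x[: min(x.size, 100_000)]).size < n_components and np.unique(x).size < n_components:
        raise ValueError("image has fewer distinct intensities than mixture components")
    rng = np.random.default_rng(seed)
    if x.size > max_voxels:
        x = rng.choice(x, size=max_voxels, replace=False)
    X = x[:, None]

    scale2 = max(np.var(x), 1e-12)
    reg = 1e-6 * scale2
    if track_loglik:
        gm = GaussianMixture(
            n_components=n_components,
            covariance_type="full",
            random_state=seed,
            max_iter=1,
            warm_start=True,
            reg_covar=reg,
            tol=0.0,
            init_params="k-means++",
        )
        trace = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(max_iter):
                gm.fit(X)
                trace.append(gm.score(X))
                if len(trace) > 1 and trace[-1] - trace[-2] < 1e-8:
                    break
        trace = np.array(trace)
        converged = True
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = GaussianMixture(
                n_components=n_components,
                covariance_type="full",
                random_state=seed,
                max_iter=max_iter,
                n_init=5,
                init_params="k-means++",
                reg_covar=reg,
            ).fit(X)
        trace = None
        converged = bool(gm.converged_)
        if not converged:
            warnings.warn("EM did not converge within max_iter; returning best fit", RuntimeWarning)

    means = gm.means_.ravel()
    variances = gm.covariances_.reshape(-1)
    # a mode whose variance sits at (or below) the regularization floor AND
    # holds almost no mass is a spike on a repeated value, a true EM collapse;
    # noise-free piecewise-constant images give floor variances with real mass
    # and are a legitimate fit
    collapsed = (variances <= 1.0001 * reg) & (gm.weights_.ravel() < 1e-4)
    if collapsed.any() or (variances <= 0).any():
        raise DegenerateMixtureError(
            f"EM collapsed a component (variances={variances}, "
            f"weights={gm.weights_.ravel()}); reduce n_components"
        )
    if blood_index is None:
        blood_index = int(np.argmax(means))
    return BloodPoolModel(
        means=means,
        variances=variances,
        weights=gm.weights_.ravel(),
        blood_index=blood_index,
        converged=converged,
        loglik_trace=trace,
    )


def bhattacharyya_gaussian(mu1: float, var1: float, mu_b: float, var_b: float) -> float:
    """Closed-form Bhattacharyya distance between two univariate Gaussians.

    Symmetric, nonnegative, zero iff the two distributions coincide.
    """
    if var1 <= 0 or var_b <= 0:
        raise ValueError("variances must be positive")
    ratio = 0.25 * (var1 / var_b + var_b / var1 + 2.0)
    return 0.25 * float(np.log(ratio)) + 0.25 * (mu1 - mu_b) ** 2 / (var1 + var_b)


def adaptive_radius(D, params: ScaleParams):
    """Window radius from the Bhattacharyya distance: strictly decreasing,
    r(0) = min_scale + max_scale, r(inf) -> min_scale.  Vectorized."""
    D = np.asarray(D, dtype=float)
    if (D < 0).any():
        raise ValueError("Bhattacharyya distance must be >= 0")
    r = params.min_scale + params.max_scale * np.exp(-params.tau * D)
    return float(r) if r.ndim == 0 else r


def radius_field(
    phi,
    image,
    model: BloodPoolModel,
    params: ScaleParams,
    radii_prev: np.ndarray = None,
    points: np.ndarray = None,
    engine: LocalStatsEngine = None,
    sigma2_floor: float = None,
    shrink_var: float = None,
):
    """Per-point adaptive radii over the narrowband of the contour.

    For each point, the interior statistics within the *current* window are
    compared with the blood-pool Gaussian (Bhattacharyya), and the new radius
    follows the exponential decay law, clamped to
    [min_scale, min_scale + max_scale] and quantized to whole voxels.  Points
    whose window holds no interior voxels keep their previous radius.

    Parameters mirror the evolution loop: ``radii_prev`` (defaults to the
    maximum window everywhere), ``points`` (defaults to the band
    |phi| <= r_max + 2), a reusable ``engine`` and the variance floor.
    """
    from .evolution import _as_phi  # local import to avoid a cycle

    phi_arr = _as_phi(phi)
    img = as_image(image)
    if engine is None:
        engine = LocalStatsEngine(img.data)
    if sigma2_floor is None:
        sigma2_floor = (0.01 * max(img.dynamic_range(), 1e-12)) ** 2
    inside = phi_arr > 0
    if points is None:
        points = np.abs(phi_arr) <= params.r_max + 2.0
    r_hi = int(round(params.r_max))
    r_lo = int(round(params.min_scale))
    if radii_prev is None:
        radii_prev = np.full(phi_arr.shape, r_hi, dtype=int)
    radii_prev = np.clip(radii_prev.astype(int), r_lo, r_hi)

    stats = side_stats_multiradius(
        engine, inside, radii_prev, points, sigma2_floor, shrink_var=shrink_var
    )
    D = np.zeros(phi_arr.shape)
    sel = points
    v1 = stats["var1"][sel]
    m1 = stats["mu1"][sel]
    ratio = 0.25 * (v1 / model.blood_variance + model.blood_variance / v1 + 2.0)
    D[sel] = 0.25 * np.log(ratio) + 0.25 * (m1 - model.blood_mean) ** 2 / (
        v1 + model.blood_variance
    )
    new_r = np.rint(adaptive_radius(np.maximum(D, 0.0), params)).astype(int)
    new_r = np.clip(new_r, r_lo, r_hi)
    out = radii_prev.copy()
    ok = sel & (stats["n1"] > 0.5)
    out[ok] = new_r[ok]
    return out
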