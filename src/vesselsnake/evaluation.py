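"""Segmentation quality metrics against a ground-truth mask.

Voxel-overlap metrics with truth R and prediction B:

    TP = |B ∩ R| / |R|      (sensitivity)
    FP = (|B| - |B ∩ R|) / |R|
    OM = 2 |B ∩ R| / (|B| + |R|)    (the Dice coefficient)

plus the symmetric Hausdorff distance between surface vertex sets extracted
by marching squares (2D) / marching cubes (3D), in physical units when a
voxel spacing is supplied.  Hausdorff is a worst-case boundary error, hence
meaningful at subvoxel resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure


@dataclass
class EvaluationReport:
    TP: float
    FP: float
    OM: float
    hausdorff: float
    n_truth: int
    n_pred: int
    units: str = "voxels"

    def to_dict(self) -> dict:
        return asdict(self)


def overlap_metrics(pred: np.ndarray, truth: np.ndarray):
    """(TP, FP, OM) voxel-overlap fractions.  Truth must be nonempty."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share a grid")
    n_r = int(truth.sum())
    if n_r == 0:
        raise ValueError("ground-truth mask is empty")
    n_b = int(pred.sum())
    if n_b == 0:
        return 0.0, 0.0, 0.0
    n_both = int((pred & truth).sum())
    tp = n_both / n_r
    fp = (n_b - n_both) / n_r
    om = 2.0 * n_both / (n_b + n_r)
    return tp, fp, om


def extract_surface(mask: np.ndarray, spacing=None) -> np.ndarray:
    """Boundary vertices of a binary mask in physical coordinates.

    2D: marching-squares contour vertices; 3D: marching-cubes mesh vertices.
    The mask is zero-padded first so objects touching the border still close.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any() or mask.all():
        raise ValueError("mask must contain both foreground and background")
    if spacing is None:
        spacing = (1.0,) * mask.ndim
    spacing = np.asarray(spacing, dtype=float)
    padded = np.pad(mask, 1).astype(float)
    if mask.ndim == 2:
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            raise ValueError("no contour found")
        verts = np.vstack(contours) - 1.0
    elif mask.ndim == 3:
        verts, _, _, _ = measure.marching_cubes(padded, 0.5)
        verts = verts - 1.0
    else:
        raise ValueError("mask must be 2D or 3D")
    return verts * spacing[None, :]


def hausdorff(X: np.ndarray, Y: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets (KD-tree based)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.size == 0 or Y.size == 0:
        raise ValueError("point sets must be nonempty")
    d_xy = cKDTree(Y).query(X)[0].max()
    d_yx = cKDTree(X).query(Y)[0].max()
    return float(max(d_xy, d_yx))


def evaluate(pred: np.ndarray, truth: np.ndarray, spacing=None) -> EvaluationReport:
    """Full report: overlap metrics + surface Hausdorff distance."""
    tp, fp, om = overlap_metrics(pred, truth)
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.any() and not pred.all():
        hd = hausdorff(extract_surface(pred, spacing), extract_surface(truth, spacing))
    else:
        hd = float("inf")
    return EvaluationReport(
        TP=tp,
        FP=fp,
        OM=om,
        hausdorff=hd,
        n_truth=int(truth.sum()),
        n_pred=int(pred.sum()),
        units="voxels" if spacing is None else "physical",
    )
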