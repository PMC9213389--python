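"""Grad-CAM++ volumetric class-activation maps and mask-coverage statistics.

The class-activation map is computed at the network's final convolutional
stage (the third residual add, a 7x7x7x64 feature grid). With the global-
average-pooling + linear head used here, the gradient of the pre-logistic
class score S with respect to a feature voxel of channel k is the constant
w_k / 343, which makes the Grad-CAM++ alpha weights available in closed
form: lifting the score through exp(S), the second and third derivatives
are exp(S) g^2 and exp(S) g^3 with g = w_k / 343, so

    alpha_k = g^2 / (2 g^2 + g^3 * sum(A_k))       (0 where the denominator is 0)
    weight_k = sum_ijk alpha_k * relu(exp(S) g)    (exp(S) > 0 cancels under
                                                    the final max-normalization)

The rectified weighted feature sum is trilinearly upsampled to the 50^3
input grid and normalized by its maximum (all-zero maps stay all-zero), so
every map lies in [0, 1]. For an ensemble the per-member maps are averaged
and re-normalized.

The mask-coverage statistic is the fraction of segmentation-mask voxels
whose class activation meets or exceeds a threshold (default 0.25).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .data_io import ModelInput
from .network import MemberNetwork

__all__ = ["HeatmapResult", "gradcampp", "mask_coverage", "cohort_coverage",
           "DEFAULT_COVERAGE_THRESHOLD", "save_heatmap", "render_overlay"]

DEFAULT_COVERAGE_THRESHOLD = 0.25
TARGET_LAYER = "add3"


@dataclass
class HeatmapResult:
    """Per-voxel class activation in [0, 1], aligned to the input grid."""

    activation: np.ndarray
    source_layer: str = TARGET_LAYER
    input_id: str = ""


def _as_array(inp) -> np.ndarray:
    if isinstance(inp, ModelInput):
        return inp.data
    return np.asarray(inp, np.float32)


def _member_map(net: MemberNetwork, x: np.ndarray) -> np.ndarray:
    A = net.final_features(x[None])[0]          # (7, 7, 7, F)
    n_vox = np.float32(A.shape[0] * A.shape[1] * A.shape[2])
    g = net.w_out / n_vox                       # dS/dA_k, constant over space
    g2, g3 = g * g, g * g * g
    denom = 2.0 * g2 + g3 * A.sum(axis=(0, 1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(np.abs(denom) > 1e-20, g2 / denom, 0.0)
    weights = n_vox * alpha * np.maximum(g, 0.0)
    cam = np.maximum(A @ weights.astype(np.float32), 0.0)
    up = ndimage.zoom(cam, 50.0 / cam.shape[0], order=1, mode="nearest",
                      grid_mode=True)
    return _max_normalize(up)


def _max_normalize(vol: np.ndarray) -> np.ndarray:
    m = float(vol.max())
    return vol / m if m > 0 else np.zeros_like(vol)


def gradcampp(net_or_ensemble, inp, input_id: str = "") -> HeatmapResult:
    """Grad-CAM++ class-activation volume for one input.

    ``net_or_ensemble`` is a :class:`MemberNetwork` or any object with a
    ``members`` list (an ensemble); for an ensemble the per-member maps are
    averaged and re-normalized. An untrained network yields a map with a
    warning — the computation is defined but not meaningful.
    """
    x = _as_array(inp)
    if x.ndim != 4:
        raise ValueError("input must be a single (50, 50, 50, c) sample")
    members = getattr(net_or_ensemble, "members", None) or [net_or_ensemble]
    if not all(m.trained for m in members):
        warnings.warn("computing a class-activation map for an untrained network",
                      stacklevel=2)
    acc = np.zeros((50, 50, 50), np.float32)
    for m in members:
        acc += _member_map(m, x)
    return HeatmapResult(activation=_max_normalize(acc / len(members)),
                         input_id=input_id)


def mask_coverage(heatmap, mask, threshold: float = DEFAULT_COVERAGE_THRESHOLD) -> float:
    """Fraction of mask voxels with class activation >= threshold (inclusive)."""
    act = heatmap.activation if isinstance(heatmap, HeatmapResult) else np.asarray(heatmap)
    mask = np.asarray(mask).astype(bool)
    if act.shape != mask.shape:
        raise ValueError("heatmap and mask grids are not congruent")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("coverage undefined for an empty mask")
    return float((act[mask] >= threshold).sum() / n)


def cohort_coverage(ensemble, X, masks, ids=None,
                    threshold: float = DEFAULT_COVERAGE_THRESHOLD):
    """Mean Grad-CAM++ mask coverage over a cohort (image-only model).

    ``X`` is (n, 50, 50, 50, 1); ``masks`` is a sequence of aligned binary
    grids (entries may be None/empty and are then excluded with a warning).
    Masks are evaluation references only — they are never model input, so
    the ensemble must be the noSEG variant. Returns (mean, per-record
    DataFrame with columns id/coverage).
    """
    variant = getattr(ensemble, "model_variant", "noSEG")
    if variant != "noSEG":
        raise ValueError("cohort coverage is defined for the image-only (noSEG) model")
    X = np.asarray(X, np.float32)
    ids = list(ids) if ids is not None else list(range(len(X)))
    rows = []
    skipped = []
    for i in range(len(X)):
        mask = masks[i]
        if mask is None or not np.asarray(mask).any():
            skipped.append(ids[i])
            continue
        hm = gradcampp(ensemble, X[i], input_id=str(ids[i]))
        rows.append({"id": ids[i], "coverage": mask_coverage(hm, mask, threshold)})
    if skipped:
        warnings.warn(f"records without a usable mask were excluded: {skipped}",
                      stacklevel=2)
    table = pd.DataFrame(rows, columns=["id", "coverage"])
    mean = float(table["coverage"].mean()) if len(table) else float("nan")
    return mean, table


def save_heatmap(path, heatmap: HeatmapResult, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write the activation volume as float32 NIfTI aligned to the input."""
    import nibabel as nib
    img = nib.Nifti1Image(heatmap.activation.astype(np.float32),
                          np.diag(list(spacing) + [1.0]))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def render_overlay(path, volume_hu: np.ndarray, heatmap: HeatmapResult) -> None:
    """Orthogonal mid-slices of the volume with the activation superimposed."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    act = heatmap.activation
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    mids = [s // 2 for s in volume_hu.shape]
    slicers = [(slice(None), slice(None), mids[2]),
               (slice(None), mids[1], slice(None)),
               (mids[0], slice(None), slice(None))]
    for ax, sl in zip(axes, slicers):
        ax.imshow(volume_hu[sl].T, cmap="gray", origin="lower",
                  vmin=-1000, vmax=400)
        ax.imshow(act[sl].T, cmap="jet", origin="lower", alpha=0.4,
                  vmin=0.0, vmax=1.0)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
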