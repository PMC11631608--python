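"""Binary vessel segmentation of 3D confocal volumes.

A deterministic classical pipeline: anisotropy-aware Gaussian smoothing,
automatic thresholding (FWHM boundary recovery or Otsu), optional multiscale
Hessian (Frangi-style) vesselness gating, and small-component removal.  All physical scales are given in
micrometres and converted per axis, because the axial voxel pitch of a
confocal stack differs from the lateral pitch.

Quality is scored with the Dice overlap coefficient against ground-truth
labels.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .synthetic import ImageVolume, LabelVolume

__all__ = ["SegmentationParams", "preprocess", "vesselness", "segment_vessels", "dice"]


@dataclass(frozen=True)
class SegmentationParams:
    """Settings for the vessel-segmentation pipeline (scales in µm).

    The default threshold rule is "fwhm": background level (volume median)
    plus ``fwhm_fraction`` of the background-to-peak dynamic range, the
    standard boundary-recovery criterion for blur-broadened vessels; "otsu"
    and fixed numeric thresholds are also accepted.  Hessian vesselness
    gating is available for low-contrast data but off by default: at
    confocal pitch the capillaries span only 1-2 lateral voxels, below the
    scale where tube filters discriminate.
    """

    gaussian_sigma: float = 0.75
    vesselness_scales: tuple[float, ...] = (2.0, 3.5, 6.0)
    #: "fwhm", "otsu", or a fixed intensity threshold
    threshold: str | float = "fwhm"
    fwhm_fraction: float = 0.4
    use_vesselness: bool = False
    vesselness_floor: float = 2e-3
    min_component_voxels: int = 64
    #: Frangi plate/blob discrimination constants
    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        scales = tuple(self.vesselness_scales)
        if not scales or any(s <= 0 for s in scales) or list(scales) != sorted(scales):
            raise ValueError("vesselness scales must be positive and ascending")
        if self.min_component_voxels < 0:
            raise ValueError("min_component_voxels must be >= 0")


def preprocess(volume: ImageVolume, sigma_um: float) -> ImageVolume:
    """Gaussian smoothing with the physical scale converted per axis.

    ``sigma_um = 0`` is the identity.
    """
    if sigma_um < 0:
        raise ValueError("sigma must be >= 0")
    data = volume.data.astype(np.float64, copy=True)
    if sigma_um > 0:
        data = ndimage.gaussian_filter(data, sigma=volume.sigma_voxels(sigma_um))
    return ImageVolume(data=data, spacing=volume.spacing, origin=volume.origin)


def vesselness(volume: ImageVolume, params: SegmentationParams) -> np.ndarray:
    """Multiscale Frangi-style vesselness for bright tubes on dark background.

    At each scale the Hessian is taken with per-axis Gaussian-derivative
    sigmas (scale in µm divided by voxel pitch) and scale-normalised with γ=2;
    the response is the maximum over scales, rescaled to [0, 1].
    """
    img = volume.data.astype(np.float64)
    response = np.zeros_like(img)
    for scale_um in params.vesselness_scales:
        sig = volume.sigma_voxels(scale_um)
        H = hessian_matrix(img, sigma=sig, order="rc", use_gaussian_derivatives=True)
        e1, e2, e3 = hessian_matrix_eigvals(H)  # sorted descending
        # scale normalisation: multiply by sigma² (geometric mean across axes)
        norm = float(np.prod(sig)) ** (2.0 / 3.0)
        e1, e2, e3 = e1 * norm, e2 * norm, e3 * norm
        # sort by absolute value: |l1| <= |l2| <= |l3|
        eigs = np.stack([e1, e2, e3])
        order = np.argsort(np.abs(eigs), axis=0)
        eigs = np.take_along_axis(eigs, order, axis=0)
        l1, l2, l3 = eigs
        with np.errstate(divide="ignore", invalid="ignore"):
            ra = np.abs(l2) / np.abs(l3)
            rb = np.abs(l1) / np.sqrt(np.abs(l2 * l3))
        s2 = e1**2 + e2**2 + e3**2
        c = 0.5 * np.sqrt(s2.max()) if s2.max() > 0 else 1.0
        v = (
            (1.0 - np.exp(-(ra**2) / (2 * params.alpha**2)))
            * np.exp(-(rb**2) / (2 * params.beta**2))
            * (1.0 - np.exp(-s2 / (2 * c**2)))
        )
        v = np.where((l2 < 0) & (l3 < 0), v, 0.0)  # bright vessels only
        v = np.nan_to_num(v)
        response = np.maximum(response, v)
    peak = response.max()
    if peak > 0:
        response /= peak
    return response


def segment_vessels(volume: ImageVolume, params: SegmentationParams | None = None) -> LabelVolume:
    """Segment vessels from a grayscale confocal-like stack.

    Deterministic: smoothing, automatic thresholding (FWHM rule by default;
    both "fwhm" and "otsu" are invariant to additive intensity shifts),
    optional vesselness gating, then removal of connected components smaller
    than ``min_component_voxels``.  Warns, but does not fail, when the
    result is empty.
    """
    params = params or SegmentationParams()
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("volume contains non-finite values")
    sm = preprocess(volume, params.gaussian_sigma)
    d = sm.data
    if params.threshold == "fwhm":
        bg = float(np.median(d))
        peak = float(np.percentile(d, 99.9))
        thr = bg + params.fwhm_fraction * (peak - bg) if peak > bg else np.inf
    elif params.threshold == "otsu":
        thr = threshold_otsu(d) if d.max() > d.min() else np.inf
    else:
        thr = float(params.threshold)
    mask = d > thr
    if params.use_vesselness:
        mask &= vesselness(sm, params) > params.vesselness_floor
    if params.min_component_voxels > 1:
        mask = remove_small_objects(mask, max_size=params.min_component_voxels - 1)
    if not mask.any():
        warnings.warn("segmentation produced an all-background mask", stacklevel=2)
    return LabelVolume(data=mask.astype(np.uint8), spacing=volume.spacing, origin=volume.origin)


def dice(a: LabelVolume, b: LabelVolume) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    am = a.data.astype(bool)
    bm = b.data.astype(bool)
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((am & bm).sum()) / denom
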