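"""Confocal colocalization pipeline for nuclear translocation.

Reproduces a deliberately simple, auditable image-analysis recipe for
two-channel (nuclear stain / protein signal) confocal z-stacks:

1. each z-slice of the nuclear-stain channel is thresholded and binarized
   independently (per-slice Otsu by default, fixed threshold optionally);
2. the binary stack is multiplied with the signal channel plane-by-plane,
   extracting signal localized to nuclei;
3. the nuclear fraction is the masked share of the signal — either of the
   summed intensity (default) or of signal-positive voxel counts ("pixel
   counting");
4. the treated/untreated ratio of nuclear fractions is the translocation
   fold change;
5. the z-dimension can be upsampled by plane replication (5x by default in
   the published rendering step) to improve definition of flattened nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "ImageStack",
    "NuclearMask",
    "NuclearFractionResult",
    "TranslocationFold",
    "binarize_nuclear",
    "mask_signal",
    "nuclear_fraction",
    "translocation_fold",
    "upsample_z",
    "per_cell_fractions",
]


@dataclass
class ImageStack:
    """A 3-D intensity grid indexed (z, y, x) with voxel calibration in µm."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (0.041, 0.232, 0.232)
    channel_label: str = "signal"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D (z, y, x) grid, got {self.voxels.ndim}-D")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size components must be > 0: {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class NuclearMask:
    """Binary nuclear volume plus a record of how it was thresholded."""

    voxels: np.ndarray
    method_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-D (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class NuclearFractionResult:
    """Share of the signal attributed to the nucleus.

    ``fraction = nuclear_signal / total_signal`` where the two totals are
    intensity sums (intensity mode) or signal-positive voxel counts
    (pixel-count mode).
    """

    nuclear_signal: float
    total_signal: float
    fraction: float
    mode: str = "intensity"
    cell_id: int | None = None


@dataclass(frozen=True)
class TranslocationFold:
    """Fold change in nuclear fraction, treated over untreated."""

    fraction_untreated: float
    fraction_treated: float
    fold: float


def _otsu_effectiveness(plane: np.ndarray, threshold: float) -> float:
    """Otsu's effectiveness metric eta: between-class variance at the chosen
    threshold over total variance, in [0, 1]."""
    fg = plane > threshold
    p1 = fg.mean()
    if p1 == 0.0 or p1 == 1.0:
        return 0.0
    delta = plane[fg].mean() - plane[~fg].mean()
    return float(p1 * (1.0 - p1) * delta**2 / plane.var())


def binarize_nuclear(
    stack: ImageStack,
    method: Literal["otsu", "fixed"] = "otsu",
    fixed_threshold: float | None = None,
    min_effectiveness: float = 0.75,
) -> NuclearMask:
    """Threshold and binarize each z-slice of the nuclear-stain channel.

    Every slice is thresholded independently (``otsu``: per-slice Otsu;
    ``fixed``: one user-supplied threshold for all slices).  A voxel enters
    the mask iff its intensity is strictly greater than the slice threshold,
    which keeps zero-background voxels out.  A constant (zero-variance)
    slice yields an all-zero mask plane.

    Otsu thresholding is meaningless on slices without foreground (it would
    binarize camera noise), so in ``otsu`` mode a slice is additionally
    zeroed when Otsu's effectiveness metric eta — between-class over total
    variance — falls below ``min_effectiveness``.  The default 0.75 sits
    safely above the eta ~0.64 that pure Gaussian noise attains while real
    nuclear cross-sections score >~0.8; pass ``min_effectiveness=0`` to
    disable the guard.  Fixed-threshold mode never applies the guard.
    """
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed thresholding requires fixed_threshold")
    elif method != "otsu":
        raise ValueError(f"unknown thresholding method {method!r}")

    mask = np.zeros(stack.shape, dtype=bool)
    thresholds: list[float | None] = []
    effectiveness: list[float | None] = []
    for z in range(stack.shape[0]):
        plane = stack.voxels[z]
        eta: float | None = None
        if method == "fixed":
            thr: float | None = float(fixed_threshold)  # type: ignore[arg-type]
        elif plane.max() == plane.min():
            thr = None  # constant slice: all-zero mask plane
        else:
            thr = float(threshold_otsu(plane))
            eta = _otsu_effectiveness(plane, thr)
            if eta < min_effectiveness:
                thr = None  # no credible foreground in this slice
        if thr is not None:
            mask[z] = plane > thr
        thresholds.append(thr)
        effectiveness.append(eta)
    return NuclearMask(
        voxels=mask,
        method_record={
            "method": method,
            "slice_thresholds": thresholds,
            "slice_effectiveness": effectiveness,
            "min_effectiveness": min_effectiveness if method == "otsu" else None,
        },
    )


def mask_signal(mask: NuclearMask, signal: ImageStack) -> ImageStack:
    """Multiply the binary mask with the signal channel plane-by-plane."""
    if mask.shape != signal.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match signal shape {signal.shape}"
        )
    return ImageStack(
        voxels=signal.voxels * mask.voxels,
        voxel_size=signal.voxel_size,
        channel_label=f"{signal.channel_label}_nuclear",
    )


def nuclear_fraction(
    signal: ImageStack,
    mask: NuclearMask,
    mode: Literal["intensity", "pixel_count"] = "intensity",
    signal_threshold: float | None = None,
) -> NuclearFractionResult:
    """Fraction of the signal channel localized to the nuclear mask.

    ``intensity`` mode (default, noise-robust): ratio of summed masked
    intensity to summed total intensity.  ``pixel_count`` mode counts
    signal-positive voxels instead; a voxel is signal-positive when its
    intensity exceeds ``signal_threshold`` (global Otsu over the signal
    volume when not given).
    """
    if mask.shape != signal.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match signal shape {signal.shape}"
        )
    if mode == "intensity":
        total = float(signal.voxels.sum())
        if total <= 0:
            raise ZeroDivisionError("nuclear fraction undefined: total signal is zero")
        nuclear = float(signal.voxels[mask.voxels].sum())
    elif mode == "pixel_count":
        if signal_threshold is None:
            v = signal.voxels
            if v.max() == v.min():
                raise ZeroDivisionError(
                    "nuclear fraction undefined: constant signal channel"
                )
            signal_threshold = float(threshold_otsu(v))
        positive = signal.voxels > signal_threshold
        total = float(positive.sum())
        if total == 0:
            raise ZeroDivisionError(
                "nuclear fraction undefined: no signal-positive voxels above "
                f"threshold {signal_threshold}"
            )
        nuclear = float((positive & mask.voxels).sum())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return NuclearFractionResult(
        nuclear_signal=nuclear,
        total_signal=total,
        fraction=nuclear / total,
        mode=mode,
    )


def translocation_fold(
    untreated: NuclearFractionResult, treated: NuclearFractionResult
) -> TranslocationFold:
    """Fold increase of the nuclear fraction upon treatment."""
    if untreated.fraction <= 0:
        raise ZeroDivisionError(
            f"translocation fold undefined: untreated fraction is "
            f"{untreated.fraction}"
        )
    return TranslocationFold(
        fraction_untreated=untreated.fraction,
        fraction_treated=treated.fraction,
        fold=treated.fraction / untreated.fraction,
    )


def upsample_z(stack: ImageStack, factor: int = 5) -> ImageStack:
    """Increase z-resolution by nearest-neighbor plane replication.

    Each plane is repeated ``factor`` times and the z voxel size divided by
    the same factor, so total intensity scales by ``factor`` and physical
    extent is preserved.  Used before 3-D surface rendering to improve the
    definition of flattened nuclei (published factor: 5).
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"upsampling factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    vz, vy, vx = stack.voxel_size
    return ImageStack(
        voxels=np.repeat(stack.voxels, factor, axis=0),
        voxel_size=(vz / factor, vy, vx),
        channel_label=stack.channel_label,
    )


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity in 3-D


def per_cell_fractions(
    mask: NuclearMask, signal: ImageStack
) -> list[NuclearFractionResult]:
    """Per-nucleus signal fractions, one result per connected mask component.

    Components are found with 26-connectivity; each cell's ``nuclear_signal``
    is the signal summed over its component and ``total_signal`` is the
    whole-field signal, so the per-cell fractions sum to the field-level
    nuclear fraction.  Supports "n cells scored" style aggregation.
    """
    if mask.shape != signal.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match signal shape {signal.shape}"
        )
    total = float(signal.voxels.sum())
    if total <= 0:
        raise ZeroDivisionError("per-cell fractions undefined: total signal is zero")
    labels, n = ndimage.label(mask.voxels, structure=_STRUCT_26)
    sums = ndimage.sum_labels(signal.voxels, labels, index=np.arange(1, n + 1))
    return [
        NuclearFractionResult(
            nuclear_signal=float(s),
            total_signal=total,
            fraction=float(s) / total,
            mode="intensity",
            cell_id=i + 1,
        )
        for i, s in enumerate(np.atleast_1d(sums))
    ]
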