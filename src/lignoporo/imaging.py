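"""Mask-based immunofluorescence quantification.

Reproduces the classic two-channel workflow for wall-localised epitopes:
z-stacks are reduced to maximum projections; a binary mask is derived from
the cell-wall counterstain channel (user threshold or Otsu) optionally inside
a hand-drawn region of interest; the mean intensity of the immunolabelled
target channel is then measured over the masked (wall-only) pixels, so that
empty lumina do not dilute the signal. Between-group comparisons are reported
as fold changes of group mean intensities with a percentile bootstrap CI over
section-level means (sections, not pixels, are the independent replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu

from .errors import DomainError, QuantificationError

__all__ = [
    "TwoChannelImageStack",
    "WallMask",
    "QuantResult",
    "RelativeIntensityResult",
    "max_project",
    "wall_mask",
    "mean_fluorescence",
    "relative_intensity",
]


@dataclass
class TwoChannelImageStack:
    """Counterstain + target z-stack, both (z, y, x) with equal shapes."""

    counterstain: np.ndarray
    target: np.ndarray
    bit_depth: int = 8
    pixel_size_um: float | None = None
    truth_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counterstain = np.asarray(self.counterstain, float)
        self.target = np.asarray(self.target, float)
        if self.counterstain.ndim != 3:
            raise DomainError("stacks must be 3-D (z, y, x)")
        if self.counterstain.shape != self.target.shape:
            raise DomainError("both channels must share one shape")
        if self.counterstain.shape[0] < 1:
            raise DomainError("stack needs >= 1 z-plane")
        top = 2**self.bit_depth - 1
        for name, ch in (("counterstain", self.counterstain), ("target", self.target)):
            if ch.min() < 0 or ch.max() > top:
                raise DomainError(f"{name} intensities outside {self.bit_depth}-bit range")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counterstain.shape


def max_project(stack: TwoChannelImageStack) -> tuple[np.ndarray, np.ndarray]:
    """Pixelwise maximum over z for each channel: (counterstain, target) 2-D."""
    return stack.counterstain.max(axis=0), stack.target.max(axis=0)


@dataclass
class WallMask:
    """Binary cell-wall mask with its provenance."""

    mask: np.ndarray
    threshold: float
    method: str  # "manual" | "otsu"
    roi: list | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 2:
            raise DomainError("mask must be 2-D")
        if not self.mask.any():
            raise QuantificationError("mask is empty (threshold too high?)")
        if self.mask.all():
            raise QuantificationError("mask covers the whole image (threshold too low?)")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def wall_mask(
    counterstain_projection: np.ndarray,
    roi: list | None = None,
    threshold: float | str = "otsu",
) -> WallMask:
    """Threshold the counterstain projection into a wall mask.

    ``threshold`` is either a manual value (pixels strictly above it are
    wall) or ``"otsu"``. ``roi`` is an optional polygon (list of (row, col)
    vertices, pixel units, even-odd fill); the mask is restricted to it.
    """
    img = np.asarray(counterstain_projection, float)
    if img.ndim != 2:
        raise DomainError("projection must be 2-D")
    region = np.ones(img.shape, bool)
    if roi is not None:
        poly = np.asarray(roi, float)
        if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
            raise DomainError("ROI polygon needs >= 3 (row, col) vertices")
        region = polygon2mask(img.shape, poly)
        if not region.any():
            raise DomainError("ROI polygon is degenerate (covers no pixels)")
    if threshold == "otsu":
        thr = float(threshold_otsu(img[region]))
        method = "otsu"
    else:
        thr = float(threshold)
        method = "manual"
    return WallMask(mask=(img > thr) & region, threshold=thr, method=method, roi=roi)


@dataclass(frozen=True)
class QuantResult:
    """Masked mean-intensity readout for one section/image."""

    mean_intensity: float
    pixel_count: int
    threshold: float
    method: str
    label: str = ""


def mean_fluorescence(target_projection: np.ndarray, mask: WallMask, label: str = "") -> QuantResult:
    """Arithmetic mean of the target channel over the masked wall pixels."""
    img = np.asarray(target_projection, float)
    if img.shape != mask.mask.shape:
        raise DomainError("target projection and mask shapes differ")
    return QuantResult(
        mean_intensity=float(img[mask.mask].mean()),
        pixel_count=mask.pixel_count,
        threshold=mask.threshold,
        method=mask.method,
        label=label,
    )


@dataclass(frozen=True)
class RelativeIntensityResult:
    """Fold change of group-mean fluorescence with a bootstrap CI."""

    fold_change: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_samples: int
    n_references: int
    aggregate: str

    def covers(self, truth: float) -> bool:
        return self.ci_low <= truth <= self.ci_high


def _group_mean(results: list[QuantResult], aggregate: str, idx=None) -> float:
    means = np.array([r.mean_intensity for r in results])
    counts = np.array([r.pixel_count for r in results], float)
    if idx is not None:
        means, counts = means[idx], counts[idx]
    if aggregate == "sections":
        return float(means.mean())
    if aggregate == "pixels":
        return float(np.average(means, weights=counts))
    raise DomainError("aggregate must be 'sections' or 'pixels'")


def relative_intensity(
    samples: list[QuantResult],
    references: list[QuantResult],
    aggregate: str = "sections",
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> RelativeIntensityResult:
    """Fold change of sample vs reference mean fluorescence.

    The point estimate is the ratio of group means (sections weighted equally
    by default, or pixel-weighted with ``aggregate="pixels"``). The CI is a
    percentile bootstrap resampling *sections* within each group — pixels
    within a section are not independent.
    """
    if not samples or not references:
        raise DomainError("each group needs >= 1 quantified section")
    ref_mean = _group_mean(references, aggregate)
    if ref_mean == 0:
        raise DomainError("reference group mean is zero; fold change undefined")
    fold = _group_mean(samples, aggregate) / ref_mean
    rng = np.random.default_rng(seed)
    ns, nr = len(samples), len(references)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        si = rng.integers(0, ns, ns)
        ri = rng.integers(0, nr, nr)
        denom = _group_mean(references, aggregate, ri)
        boots[b] = _group_mean(samples, aggregate, si) / denom if denom else np.nan
    lo, hi = np.nanpercentile(boots, [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100])
    return RelativeIntensityResult(
        fold_change=float(fold),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        n_samples=ns,
        n_references=nr,
        aggregate=aggregate,
    )
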