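"""Voxel-wise two-sample t-maps, thresholded masks, and mask perturbations.

The t-map is the absolute per-voxel two-sample t statistic between the two
groups of a *training* cohort, optionally after Gaussian smoothing of each
volume.  Thresholding it yields the t-mask used for feature selection; the
perturbation operations implement the robustness controls (Gaussian noise on
the map, Bernoulli knockout of the mask, and a purely random mask baseline).

Two statistic modes are provided:

``standard`` (default)
    The equal-variance two-sample t statistic,
    |mu0 - mu1| / sqrt(s_p^2 (1/n0 + 1/n1)), with pooled variance s_p^2 on
    n0+n1-2 degrees of freedom.  Under the per-voxel null this follows a
    Student t distribution, so thresholds are on the familiar t scale.

``literal``
    An effect-size-like variant without the sample-size factor,
    |mu0 - mu1| / sqrt(0.5 (s0^2 + s1^2)).

Sample standard deviations use divisor n-1 in both modes.  Voxels outside the
brain support, or with zero within-group variance, are set to 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .cohort import BinaryMask, CohortError, VolumeStack, write_mask, write_volume

__all__ = [
    "SmoothingSpec",
    "TMap",
    "fwhm_to_sigma",
    "smooth_volume",
    "compute_tmap",
    "threshold_mask",
    "perturb_tmap_gaussian",
    "perturb_mask_bernoulli",
    "random_mask",
    "apply_mask",
    "selection_rate",
    "write_tmap",
]

#: FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_SIGMA_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Convert a Gaussian FWHM in mm to a kernel sigma in voxel units."""
    return (fwhm_mm / voxel_size_mm) / FWHM_SIGMA_FACTOR


@dataclass(frozen=True)
class SmoothingSpec:
    """Isotropic-in-mm Gaussian smoothing, specified by FWHM.

    The per-axis sigma in voxels is ``(fwhm_mm / voxel_size_mm[axis]) /
    (2 sqrt(2 ln 2))``, so anisotropic voxels get anisotropic sigmas.
    """

    fwhm_mm: float = 6.0

    def __post_init__(self):
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")

    def sigmas_vox(self, voxel_sizes_mm) -> np.ndarray:
        vox = np.asarray(voxel_sizes_mm, dtype=float).reshape(3)
        return np.array([fwhm_to_sigma(self.fwhm_mm, v) for v in vox])


@dataclass(frozen=True)
class TMap:
    """A non-negative per-voxel statistic map on the cohort grid."""

    grid: np.ndarray
    mode: str  # {"literal", "standard"}
    fwhm_mm: float
    n0: int
    n1: int
    brain_mask: BinaryMask

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=np.float64)
        if (g < 0).any():
            raise ValueError("t-map values must be non-negative")
        object.__setattr__(self, "grid", g)

    @property
    def support(self) -> np.ndarray:
        return self.brain_mask.astype_bool()


def smooth_volume(volume: np.ndarray, spec: SmoothingSpec, voxel_sizes_mm) -> np.ndarray:
    """Gaussian-smooth one 3D volume; FWHM 0 is the identity.

    Boundary handling is nearest-edge replication, which preserves total
    intensity for interior impulses.
    """
    if spec.fwhm_mm == 0:
        return np.asarray(volume, dtype=np.float64)
    sigmas = spec.sigmas_vox(voxel_sizes_mm)
    return ndimage.gaussian_filter(np.asarray(volume, dtype=np.float64), sigma=sigmas, mode="nearest")


def compute_tmap(
    train_stack: VolumeStack,
    brain_mask: BinaryMask,
    spec: SmoothingSpec | None = None,
    mode: str = "standard",
) -> TMap:
    """Compute the smoothed voxel-wise two-sample t-map on training data.

    Callers must pass *training* subjects only: the map drives feature
    selection applied to validation and test volumes, so computing it on
    anything but the training split would leak outcome information.
    """
    if mode not in ("literal", "standard"):
        raise ValueError(f"unknown t-map mode {mode!r}")
    spec = spec if spec is not None else SmoothingSpec()
    labels = train_stack.labels
    if len(np.unique(labels)) < 2:
        raise CohortError("one-group error: training set must contain both labels")
    g0 = train_stack.group(0)
    g1 = train_stack.group(1)
    n0, n1 = g0.shape[0], g1.shape[0]
    if n0 < 2 or n1 < 2:
        raise CohortError("insufficient samples: need at least 2 subjects per group")

    if spec.fwhm_mm > 0:
        g0 = np.stack([smooth_volume(v, spec, train_stack.voxel_sizes_mm) for v in g0])
        g1 = np.stack([smooth_volume(v, spec, train_stack.voxel_sizes_mm) for v in g1])

    mu0, mu1 = g0.mean(axis=0), g1.mean(axis=0)
    var0 = g0.var(axis=0, ddof=1)
    var1 = g1.var(axis=0, ddof=1)
    num = np.abs(mu0 - mu1)
    if mode == "literal":
        denom_sq = 0.5 * (var0 + var1)
    else:
        sp2 = ((n0 - 1) * var0 + (n1 - 1) * var1) / (n0 + n1 - 2)
        denom_sq = sp2 * (1.0 / n0 + 1.0 / n1)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(denom_sq)
    t[denom_sq == 0] = 0.0  # zero-variance voxels are excluded, not infinite
    t[~brain_mask.astype_bool()] = 0.0
    return TMap(grid=t, mode=mode, fwhm_mm=spec.fwhm_mm, n0=n0, n1=n1, brain_mask=brain_mask)


def threshold_mask(tmap: TMap, threshold: float) -> BinaryMask:
    """Binarize a t-map: a voxel is selected iff t(v) > threshold (strict)
    and lies in the brain support.

    At threshold 0 this selects the whole brain minus voxels whose statistic
    is exactly 0 (zero variance or identical group means), i.e. the entire
    brain mask in any non-degenerate cohort; beyond the map maximum the mask
    is empty.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    grid = ((tmap.grid > threshold) & tmap.support).astype(np.uint8)
    return BinaryMask(grid=grid, provenance="tmask", params={"threshold": float(threshold)})


def perturb_tmap_gaussian(tmap: TMap, sd: float, seed: int) -> TMap:
    """Corrupt the t-map with i.i.d. Normal(0, sd) noise inside the brain
    support, clipping negative results to 0 (the map is an absolute statistic).
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return tmap
    rng = np.random.default_rng(seed)
    sel = tmap.support
    grid = tmap.grid.copy()
    grid[sel] = np.clip(grid[sel] + rng.normal(0.0, sd, size=int(sel.sum())), 0.0, None)
    return replace(tmap, grid=grid)


def perturb_mask_bernoulli(mask: BinaryMask, p: float, seed: int) -> BinaryMask:
    """Randomly knock out active mask voxels, each independently with
    probability ``p`` (Bernoulli knockout); inactive voxels stay 0.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    grid = mask.grid.copy()
    active = grid.astype(bool)
    knockout = rng.random(int(active.sum())) < p
    vals = grid[active]
    vals[knockout] = 0
    grid[active] = vals
    return BinaryMask(grid=grid, provenance="tmask_bernoulli", params={**mask.params, "p": float(p)})


def random_mask(brain_mask: BinaryMask, p: float, seed: int) -> BinaryMask:
    """Draw a single random mask over the brain: each brain voxel is kept with
    probability 1-p.  The draw is made once per run and applied unchanged to
    train, validation and test — the random analogue of a t-mask.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sel = brain_mask.astype_bool()
    grid = np.zeros_like(brain_mask.grid)
    grid[sel] = (rng.random(int(sel.sum())) >= p).astype(np.uint8)
    return BinaryMask(grid=grid, provenance="random", params={"p": float(p)})


def apply_mask(stack: VolumeStack, mask: BinaryMask) -> VolumeStack:
    """Multiply every volume elementwise by the binary mask.

    Spatial relationships are preserved (no vectorization or cropping), and
    labels/ids are untouched: masked-out voxels carry value 0 into the
    classifier, realizing the redundant-feature suppression of t-masking.
    """
    if mask.grid.shape != stack.grid_shape:
        raise CohortError("inconsistent grid: mask shape does not match cohort")
    m = mask.grid.astype(np.float64)
    return replace(stack, volumes=stack.volumes * m[None, ...])


def selection_rate(mask: BinaryMask, brain_mask: BinaryMask) -> float:
    """Fraction of brain voxels retained by the mask."""
    n_brain = brain_mask.n_active
    if n_brain == 0:
        raise ValueError("empty brain mask")
    return mask.n_active / n_brain


def write_tmap(tmap: TMap, affine: np.ndarray, path: str | Path, seed: int | None = None) -> Path:
    """Write a t-map as float32 NIfTI plus a JSON sidecar with its metadata."""
    path = Path(path)
    write_volume(tmap.grid, affine, path)
    sidecar = path.with_name(path.name.removesuffix(".gz").removesuffix(".nii") + ".json")
    meta = {"mode": tmap.mode, "fwhm_mm": tmap.fwhm_mm, "n0": tmap.n0, "n1": tmap.n1}
    if seed is not None:
        meta["seed"] = seed
    sidecar.write_text(json.dumps(meta, indent=2))
    return path
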