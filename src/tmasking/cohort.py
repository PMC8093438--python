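"""Cohort containers and NIfTI / participants-table I/O.

A cohort is an ordered stack of co-registered 3D intensity volumes (one per
subject) living on a single voxel grid, with binary group labels.  Volumes are
assumed spatially normalized upstream (same grid, same affine); this module
validates that assumption rather than performing registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeStack",
    "BinaryMask",
    "CohortError",
    "read_cohort",
    "znormalize",
    "write_volume",
    "write_mask",
    "read_mask",
]


class CohortError(ValueError):
    """Raised for inconsistent grids, malformed participants tables or labels."""


MASK_PROVENANCES = (
    "brain",
    "tmask",
    "tmask_noise",
    "tmask_bernoulli",
    "random",
    "region_truth",
)


@dataclass(frozen=True)
class BinaryMask:
    """A per-voxel {0,1} map on the cohort grid.

    Parameters
    ----------
    grid : ndarray of uint8/bool, 3D
        Voxel indicator; strictly 0/1.
    provenance : str
        One of ``brain``, ``tmask``, ``tmask_noise``, ``tmask_bernoulli``,
        ``random``, ``region_truth``.
    params : dict
        Threshold / probability used to derive the mask, for the sidecar.
    """

    grid: np.ndarray
    provenance: str = "brain"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 3:
            raise CohortError("mask grid must be 3D")
        vals = np.unique(g)
        if not np.isin(vals, (0, 1)).all():
            raise CohortError(f"mask values must be in {{0,1}}, got {vals}")
        if self.provenance not in MASK_PROVENANCES:
            raise CohortError(f"unknown mask provenance {self.provenance!r}")
        object.__setattr__(self, "grid", g.astype(np.uint8))

    @property
    def n_active(self) -> int:
        return int(self.grid.sum())

    def astype_bool(self) -> np.ndarray:
        return self.grid.astype(bool)


@dataclass(frozen=True)
class VolumeStack:
    """An ordered cohort of same-shape 3D volumes with binary labels.

    Invariants: all volumes share one shape and affine, labels are in {0,1}
    with one per volume, and subject ids are unique.
    """

    volumes: np.ndarray  # (n_subjects, X, Y, Z) float
    labels: np.ndarray  # (n_subjects,) in {0,1}
    subject_ids: tuple[str, ...]
    affine: np.ndarray  # 4x4
    voxel_sizes_mm: np.ndarray  # (3,)

    def __post_init__(self):
        vols = np.asarray(self.volumes, dtype=np.float64)
        labels = np.asarray(self.labels)
        if vols.ndim != 4:
            raise CohortError("volumes must stack to a 4D array (n, X, Y, Z)")
        if len(labels) != vols.shape[0]:
            raise CohortError("label error: labels length != number of volumes")
        if not np.isin(labels, (0, 1)).all():
            raise CohortError(f"label error: labels must be binary, got {np.unique(labels)}")
        ids = tuple(str(s) for s in self.subject_ids)
        if len(set(ids)) != len(ids):
            raise CohortError("participants table error: duplicate subject ids")
        if len(ids) != vols.shape[0]:
            raise CohortError("participants table error: ids length != number of volumes")
        vox = np.asarray(self.voxel_sizes_mm, dtype=float).reshape(3)
        if (vox <= 0).any():
            raise CohortError("voxel sizes must be positive")
        object.__setattr__(self, "volumes", vols)
        object.__setattr__(self, "labels", labels.astype(np.int64))
        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float).reshape(4, 4))
        object.__setattr__(self, "voxel_sizes_mm", vox)

    def __len__(self) -> int:
        return self.volumes.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.volumes.shape[1:])

    def subset(self, indices: Sequence[int]) -> "VolumeStack":
        idx = np.asarray(list(indices), dtype=int)
        return VolumeStack(
            volumes=self.volumes[idx],
            labels=self.labels[idx],
            subject_ids=tuple(self.subject_ids[i] for i in idx),
            affine=self.affine,
            voxel_sizes_mm=self.voxel_sizes_mm,
        )

    def group(self, label: int) -> np.ndarray:
        """Volumes of one class, stacked (n_label, X, Y, Z)."""
        return self.volumes[self.labels == label]


def _voxel_sizes_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


def read_cohort(
    volume_paths: Sequence[str | Path],
    participants: str | Path,
    brain_mask: str | Path | None = None,
) -> tuple[VolumeStack, BinaryMask | None]:
    """Assemble a validated cohort from NIfTI files and a participants TSV.

    The TSV must have columns ``subject_id`` and ``label``; volume files are
    matched to rows one-to-one by the order of ``volume_paths`` against the
    subject id embedded in each file stem (``<subject_id>*.nii[.gz]``) when
    possible, else by row order.  Shape or affine mismatches across files are
    rejected ("inconsistent grid").
    """
    table = pd.read_csv(participants, sep="\t", dtype={"subject_id": str})
    for col in ("subject_id", "label"):
        if col not in table.columns:
            raise CohortError(f"participants table error: missing column {col!r}")
    if table["subject_id"].duplicated().any():
        raise CohortError("participants table error: duplicate subject ids")
    if len(volume_paths) != len(table):
        raise CohortError(
            "participants table error: "
            f"{len(volume_paths)} volumes vs {len(table)} table rows"
        )
    labels_by_id = dict(zip(table["subject_id"], table["label"]))

    vols, ids, labels = [], [], []
    ref_affine = None
    ref_shape = None
    for i, p in enumerate(volume_paths):
        p = Path(p)
        img = nib.load(str(p))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        stem = p.name.removesuffix(".gz").removesuffix(".nii")
        sid = stem if stem in labels_by_id else str(table["subject_id"].iloc[i])
        if sid not in labels_by_id:
            raise CohortError(f"participants table error: no row for volume {p.name}")
        if ref_affine is None:
            ref_affine, ref_shape = img.affine, data.shape
        else:
            if data.shape != ref_shape or not np.allclose(img.affine, ref_affine):
                raise CohortError(f"inconsistent grid: {p.name} does not match the cohort grid")
        vols.append(data)
        ids.append(sid)
        labels.append(labels_by_id[sid])

    stack = VolumeStack(
        volumes=np.stack(vols),
        labels=np.asarray(labels),
        subject_ids=tuple(ids),
        affine=ref_affine,
        voxel_sizes_mm=_voxel_sizes_from_affine(ref_affine),
    )
    mask = None
    if brain_mask is not None:
        mask = read_mask(brain_mask, provenance="brain")
        if mask.grid.shape != stack.grid_shape:
            raise CohortError("inconsistent grid: brain mask shape does not match cohort")
    return stack, mask


def znormalize(stack: VolumeStack, within_mask: BinaryMask | None = None) -> VolumeStack:
    """Rescale each volume independently to zero mean, unit standard deviation.

    The normalization support is the whole volume, or the brain-mask voxels if
    ``within_mask`` is given (voxels outside the mask are then zeroed).  The
    standard deviation uses the population convention (divide by the voxel
    count).  Idempotent, and invariant to affine intensity changes a*x+b, a>0.
    """
    out = np.empty_like(stack.volumes)
    if within_mask is not None:
        sel = within_mask.astype_bool()
        if sel.shape != stack.grid_shape:
            raise CohortError("inconsistent grid: mask shape does not match cohort")
        if not sel.any():
            raise CohortError("degenerate volume: empty normalization support")
    for i, vol in enumerate(stack.volumes):
        support = vol[sel] if within_mask is not None else vol
        mu = support.mean()
        sd = support.std()  # ddof=0: population convention
        if sd == 0:
            raise CohortError(f"degenerate volume: zero variance for subject {stack.subject_ids[i]}")
        if within_mask is not None:
            v = np.zeros_like(vol)
            v[sel] = (vol[sel] - mu) / sd
        else:
            v = (vol - mu) / sd
        out[i] = v
    return replace(stack, volumes=out)


def write_volume(grid: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a 3D float volume as NIfTI-1 (float32)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))
    return path


def write_mask(mask: BinaryMask, affine: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as NIfTI-1 uint8; values are validated by BinaryMask."""
    path = Path(path)
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), np.asarray(affine))
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, provenance: str = "brain") -> BinaryMask:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    return BinaryMask(grid=(data > 0.5).astype(np.uint8), provenance=provenance)
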