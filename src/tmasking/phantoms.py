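"""Synthetic brain-phantom cohorts with planted group differences.

The generator emulates the statistical structure of a spatially normalized
T1-weighted cohort at desk scale: an ellipsoidal "brain" filled with a shared
smoothed random-field tissue texture, per-subject i.i.d. Gaussian noise, and a
compact set of effect regions (spheres) inside which group-1 subjects receive
a uniform intensity decrement — an atrophy-like hypointensity.  The decrement
is ``effect_size * noise_sd``, so the per-voxel Cohen's d inside the regions
equals ``effect_size`` by construction, making parameter recovery and type-I
calibration quantitative.

Subject noise is spatially independent by default, so the standard-mode
t-map's null distribution is the textbook Student t; a ``noise_fwhm_mm``
option smooths the noise fields to mimic the spatial correlation of real
registered data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .cohort import BinaryMask, VolumeStack, write_mask, write_volume
from .tmap import SmoothingSpec, smooth_volume

__all__ = ["PhantomSpec", "region_mask", "brain_mask_for", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of a synthetic cohort.

    Defaults give a 32^3 grid of 3 mm voxels, a brain ellipsoid of semi-axes
    (13, 11, 10) voxels (~6000 brain voxels), four effect spheres totalling
    about 10% of the brain, effect size (Cohen's d) 1.2 and 40 subjects per
    group — the regime in which a fraction of roughly one tenth of the brain
    carries the discriminative signal.
    """

    grid_dims: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 3.0
    brain_semiaxes_vox: tuple[float, float, float] = (13.0, 11.0, 10.0)
    texture_sd: float = 0.2
    texture_fwhm_mm: float = 6.0
    noise_sd: float = 0.1
    #: effect spheres as (center_x, center_y, center_z, radius), voxel units;
    #: None -> a default layout targeting ``target_fraction`` of the brain.
    regions: tuple[tuple[float, float, float, float], ...] | None = None
    target_fraction: float = 0.10
    effect_size: float = 1.2
    n_per_group: int = 40
    base_intensity: float = 1.0
    #: 0 -> spatially independent subject noise (textbook t null)
    noise_fwhm_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0.0 < self.target_fraction < 1.0:
            raise ValueError("target_fraction must be in (0, 1)")


def _ellipsoid(dims, center, semiaxes) -> np.ndarray:
    coords = np.indices(dims).astype(float)
    d2 = sum(((coords[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def brain_mask_for(spec: PhantomSpec) -> BinaryMask:
    """The brain support: an ellipsoid centered on the grid."""
    dims = spec.grid_dims
    center = [(d - 1) / 2.0 for d in dims]
    grid = _ellipsoid(dims, center, spec.brain_semiaxes_vox)
    return BinaryMask(grid=grid.astype(np.uint8), provenance="brain")


def _default_regions(spec: PhantomSpec, brain: np.ndarray) -> tuple[tuple[float, float, float, float], ...]:
    """A fixed layout of four spheres sized to hit ``target_fraction``.

    Sphere centers sit at deterministic offsets inside the brain; a shared
    radius is solved numerically so the voxelized union covers the target
    fraction of brain voxels.
    """
    cx, cy, cz = [(d - 1) / 2.0 for d in spec.grid_dims]
    ax, ay, az = spec.brain_semiaxes_vox
    centers = [
        (cx + 0.45 * ax, cy + 0.25 * ay, cz),
        (cx - 0.45 * ax, cy - 0.25 * ay, cz + 0.2 * az),
        (cx, cy + 0.45 * ay, cz - 0.35 * az),
        (cx - 0.2 * ax, cy - 0.1 * ay, cz - 0.45 * az),
    ]
    target = spec.target_fraction * brain.sum()

    def coverage(r: float) -> int:
        m = np.zeros(spec.grid_dims, dtype=bool)
        for c in centers:
            m |= _ellipsoid(spec.grid_dims, c, (r, r, r))
        return int((m & brain).sum())

    lo, hi = 0.5, min(spec.brain_semiaxes_vox)
    for _ in range(40):  # bisection on the shared radius
        mid = 0.5 * (lo + hi)
        if coverage(mid) < target:
            lo = mid
        else:
            hi = mid
    r = 0.5 * (lo + hi)
    return tuple((c[0], c[1], c[2], r) for c in centers)


def region_mask(spec: PhantomSpec) -> BinaryMask:
    """Voxelized union of the effect regions, clipped to the brain.

    Warns if the achieved brain fraction misses ``target_fraction`` by more
    than 20% relative.
    """
    brain = brain_mask_for(spec).astype_bool()
    regions = spec.regions if spec.regions is not None else _default_regions(spec, brain)
    m = np.zeros(spec.grid_dims, dtype=bool)
    for (x, y, z, r) in regions:
        m |= _ellipsoid(spec.grid_dims, (x, y, z), (max(r, 1e-9),) * 3)
    if (m & ~brain).any() and spec.regions is not None:
        raise ValueError("spec error: effect regions exceed the brain support")
    m &= brain
    frac = m.sum() / brain.sum()
    if abs(frac - spec.target_fraction) > 0.2 * spec.target_fraction:
        import warnings

        warnings.warn(
            f"achieved region fraction {frac:.3f} deviates >20% from target "
            f"{spec.target_fraction:.3f}",
            stacklevel=2,
        )
    return BinaryMask(grid=m.astype(np.uint8), provenance="region_truth")


def generate_cohort(spec: PhantomSpec) -> tuple[VolumeStack, BinaryMask, BinaryMask]:
    """Generate a balanced phantom cohort.

    Returns ``(stack, brain_mask, region_truth)``.  One shared template (base
    tissue + smoothed random field inside the brain, 0 outside) underlies all
    subjects; each subject adds an independent noise field, and group-1
    subjects additionally get ``-effect_size * noise_sd`` inside the effect
    regions.  Everything is reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    brain_bm = brain_mask_for(spec)
    brain = brain_bm.astype_bool()
    region_bm = region_mask(spec)
    region = region_bm.astype_bool()

    texture = rng.normal(0.0, 1.0, size=spec.grid_dims)
    if spec.texture_fwhm_mm > 0:
        texture = smooth_volume(
            texture, SmoothingSpec(spec.texture_fwhm_mm), (spec.voxel_size_mm,) * 3
        )
        texture /= max(texture.std(), 1e-12)  # restore unit scale after smoothing
    template = np.zeros(spec.grid_dims)
    template[brain] = spec.base_intensity + spec.texture_sd * texture[brain]

    n = spec.n_per_group
    decrement = spec.effect_size * spec.noise_sd
    vols = np.zeros((2 * n,) + tuple(spec.grid_dims))
    labels = np.zeros(2 * n, dtype=int)
    labels[n:] = 1
    for i in range(2 * n):
        noise = rng.normal(0.0, 1.0, size=spec.grid_dims)
        if spec.noise_fwhm_mm > 0:
            noise = smooth_volume(
                noise, SmoothingSpec(spec.noise_fwhm_mm), (spec.voxel_size_mm,) * 3
            )
            noise /= max(noise.std(), 1e-12)
        vol = template.copy()
        vol[brain] += spec.noise_sd * noise[brain]
        if labels[i] == 1:
            vol[region] -= decrement
        vols[i] = vol

    ids = tuple(f"sub-{'nc' if l == 0 else 'eff'}{i:03d}" for i, l in enumerate(labels))
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    stack = VolumeStack(
        volumes=vols,
        labels=labels,
        subject_ids=ids,
        affine=affine,
        voxel_sizes_mm=np.array([spec.voxel_size_mm] * 3),
    )
    return stack, brain_bm, region_bm


def write_cohort(spec: PhantomSpec, out_dir: str | Path) -> Path:
    """Write the standard cohort layout: per-subject NIfTI volumes,
    participants.tsv, brain_mask.nii.gz, region_truth.nii.gz and spec.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, brain_bm, region_bm = generate_cohort(spec)
    rows = []
    for i, sid in enumerate(stack.subject_ids):
        write_volume(stack.volumes[i], stack.affine, out / f"{sid}.nii.gz")
        rows.append(f"{sid}\t{stack.labels[i]}")
    (out / "participants.tsv").write_text("subject_id\tlabel\n" + "\n".join(rows) + "\n")
    write_mask(brain_bm, stack.affine, out / "brain_mask.nii.gz")
    write_mask(region_bm, stack.affine, out / "region_truth.nii.gz")
    d = asdict(spec)
    (out / "spec.json").write_text(json.dumps(d, indent=2, default=list))
    return out
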