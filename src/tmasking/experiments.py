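"""Experimental design: stratified splits, the seven model configurations,
validation curves over repeated split permutations, and their aggregation.

Seven configurations are supported, identified by short ids:

========  ==============================================================
id        meaning
========  ==============================================================
raw       CNN on unmasked volumes (no feature selection)
norm      CNN on whole-brain-masked volumes (threshold-0 mask)
fs_cnn    CNN with the thresholded t-mask, swept over thresholds
fs_linear mean-intensity linear classifier with the t-mask
fs_noise  t-map corrupted with Gaussian noise (sd 0.2) before thresholding
fs_bernoulli  t-mask with Bernoulli knockout (p = 0.05) after thresholding
fs_random a fixed random mask; the sweep variable is the drop probability p
========  ==============================================================

Every experimental point averages metrics over repeated random split
permutations (5 by default).  Two aggregation schemes are provided:
*average* cross-validation (mean test metric across permutations, spread as
the standard deviation of the mean) and *classical* cross-validation (test
metric of the permutation/grid point with the best validation metric).

On phantom cohorts, which are born co-registered, ``raw`` and ``norm``
coincide up to the whole-brain mask; the distinction is kept for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .cohort import BinaryMask, VolumeStack, znormalize
from .nn import CnnConfig, TrainingSchedule, build_cnn, linear_baseline, stack_to_tensor, train
from .tmap import (
    SmoothingSpec,
    apply_mask,
    compute_tmap,
    perturb_mask_bernoulli,
    perturb_tmap_gaussian,
    random_mask,
    selection_rate,
    threshold_mask,
)

__all__ = [
    "CONFIG_IDS",
    "SplitSpec",
    "Metrics",
    "ValidationCurve",
    "split_dataset",
    "threshold_grid",
    "probability_grid",
    "evaluate",
    "run_configuration",
    "aggregate_average_cv",
    "aggregate_classical_cv",
    "performance_enhancement",
    "dice",
]

CONFIG_IDS = ("raw", "norm", "fs_cnn", "fs_linear", "fs_noise", "fs_bernoulli", "fs_random")

#: perturbation magnitudes of the two robustness configurations
NOISE_SD = 0.2
BERNOULLI_P = 0.05


@dataclass(frozen=True)
class SplitSpec:
    """Balanced, disjoint, exhaustive train/validation/test assignment."""

    fractions: tuple[float, float, float]
    seed: int
    assignment: dict  # subject id -> {"train", "val", "test"}

    def indices(self, stack: VolumeStack, subset: str) -> list[int]:
        return [i for i, sid in enumerate(stack.subject_ids) if self.assignment[sid] == subset]


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    auc: float
    probabilities: np.ndarray = field(repr=False, default=None)


def split_dataset(
    stack: VolumeStack,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitSpec:
    """Randomly assign subjects to train/val/test with equal class counts in
    every subset.  Requires ``fraction * n_per_class`` to be integral."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = stack.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts[0] != counts[1]:
        raise ValueError("split requires a balanced two-class cohort")
    n_class = counts[0]
    sizes = []
    for f in fractions[:-1]:
        s = f * n_class
        if abs(s - round(s)) > 1e-9:
            raise ValueError(
                "split arithmetic error: fraction "
                f"{f} of {n_class} per-class subjects is not integral; "
                "adjust fractions or cohort size"
            )
        sizes.append(int(round(s)))
    sizes.append(n_class - sum(sizes))

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        start = 0
        for name, size in zip(("train", "val", "test"), sizes):
            for i in idx[start : start + size]:
                assignment[stack.subject_ids[i]] = name
            start += size
    return SplitSpec(fractions=tuple(fractions), seed=seed, assignment=assignment)


def threshold_grid(lo: float = 0.0, hi: float = 8.0, n_points: int = 21) -> np.ndarray:
    """Equally spaced thresholds inclusive of both endpoints (default step 0.4,
    from the whole brain at 0 to no surviving voxels at 8)."""
    if not (lo < hi and n_points >= 2):
        raise ValueError("need lo < hi and n_points >= 2")
    return np.linspace(lo, hi, n_points)


def probability_grid(lo: float = 0.01, hi: float = 0.99, n_points: int = 21) -> np.ndarray:
    """Drop-probability sweep for the random-mask configuration."""
    if not (lo < hi and n_points >= 2):
        raise ValueError("need lo < hi and n_points >= 2")
    return np.linspace(lo, hi, n_points)


def evaluate(probabilities: np.ndarray, labels: np.ndarray) -> Metrics:
    """Accuracy at the 0.5 probability cutoff and the ROC AUC (probability a
    positive outranks a negative, ties counted 1/2)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if len(p) != len(y):
        raise ValueError("probabilities and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    acc = float(np.mean((p > 0.5) == (y == 1)))
    auc = float(roc_auc_score(y, p))
    return Metrics(accuracy=acc, auc=auc, probabilities=p)


@dataclass
class ValidationCurve:
    """Per-(grid point, permutation) metrics for one configuration."""

    config_id: str
    sweep_name: str  # "threshold" or "p"
    grid: np.ndarray
    records: pd.DataFrame
    # columns: grid_value, seed, split, accuracy, auc, selection_rate, degenerate
    models: dict = field(default_factory=dict)  # (grid_value, seed) -> fitted classifier
    masks: dict = field(default_factory=dict)  # (grid_value, seed) -> BinaryMask


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _train_and_score(
    config_id: str,
    masked: VolumeStack,
    split: SplitSpec,
    mask: BinaryMask | None,
    model_config: CnnConfig,
    schedule: TrainingSchedule,
    perm_seed: int,
) -> dict[str, Metrics]:
    tr = masked.subset(split.indices(masked, "train"))
    va = masked.subset(split.indices(masked, "val"))
    te = masked.subset(split.indices(masked, "test"))
    if config_id == "fs_linear":
        model = linear_baseline(tr, mask)
        probs = {s: model.predict_proba(st) for s, st in (("train", tr), ("val", va), ("test", te))}
    else:
        model = build_cnn(model_config, seed=perm_seed)
        sched = TrainingSchedule(**{**schedule.__dict__, "seed": perm_seed})
        train(model, tr, va, sched)
        probs = {}
        for s, st in (("train", tr), ("val", va), ("test", te)):
            x, _ = stack_to_tensor(st)
            probs[s] = model.predict_proba(x)
    metrics = {s: evaluate(probs[s], st.labels) for (s, st) in (("train", tr), ("val", va), ("test", te))}
    return metrics, model


def run_configuration(
    config_id: str,
    cohort: VolumeStack,
    brain_mask: BinaryMask,
    grid: np.ndarray | None = None,
    n_permutations: int = 5,
    master_seed: int = 0,
    model_config: CnnConfig | None = None,
    schedule: TrainingSchedule | None = None,
    tmap_mode: str = "standard",
    fwhm_mm: float = 6.0,
    normalize: bool = True,
    noise_sd: float = NOISE_SD,
    bernoulli_p: float = BERNOULLI_P,
    keep_models: bool = False,
) -> ValidationCurve:
    """Run one of the seven configurations over repeated split permutations.

    For feature-selection configurations the t-map is computed on the training
    subset of each permutation only, then the resulting mask is applied to all
    three subsets.  An empty mask at a grid point records chance-level metrics
    with a ``degenerate`` flag rather than aborting the sweep.
    """
    if config_id not in CONFIG_IDS:
        raise ValueError(f"unknown configuration {config_id!r}")
    model_config = model_config or CnnConfig(input_shape=cohort.grid_shape)
    schedule = schedule or TrainingSchedule()
    if normalize:
        cohort = znormalize(cohort)

    sweep_name = "p" if config_id == "fs_random" else "threshold"
    if config_id in ("raw", "norm"):
        grid = np.array([0.0])  # single experimental point
    elif grid is None:
        grid = probability_grid() if config_id == "fs_random" else threshold_grid()
    grid = np.asarray(grid, dtype=float)

    seeds = _derive_seeds(master_seed, n_permutations)
    smoothing = SmoothingSpec(fwhm_mm)
    rows = []
    models: dict = {}
    masks: dict = {}
    for perm, seed in enumerate(seeds):
        split = split_dataset(cohort, seed=seed)
        tmap = None
        if config_id in ("fs_cnn", "fs_linear", "fs_noise", "fs_bernoulli"):
            train_subset = cohort.subset(split.indices(cohort, "train"))
            tmap = compute_tmap(train_subset, brain_mask, smoothing, mode=tmap_mode)
            if config_id == "fs_noise":
                tmap = perturb_tmap_gaussian(tmap, noise_sd, seed=seed + 1)
        for gi, g in enumerate(grid):
            degenerate = False
            if config_id == "raw":
                mask = None
                masked = cohort
            elif config_id == "norm":
                mask = brain_mask
                masked = apply_mask(cohort, mask)
            elif config_id == "fs_random":
                mask = random_mask(brain_mask, g, seed=seed + 2)
                masked = apply_mask(cohort, mask)
            else:
                mask = threshold_mask(tmap, g)
                if config_id == "fs_bernoulli":
                    mask = perturb_mask_bernoulli(mask, bernoulli_p, seed=seed + 3)
                masked = apply_mask(cohort, mask)
            sel = selection_rate(mask, brain_mask) if mask is not None else 1.0
            if mask is not None and mask.n_active == 0:
                degenerate = True
                metrics = {s: Metrics(0.5, 0.5) for s in ("train", "val", "test")}
            else:
                metrics, model = _train_and_score(
                    config_id, masked, split, mask, model_config, schedule, seed
                )
                if keep_models:
                    models[(float(g), seed)] = model
                    masks[(float(g), seed)] = mask
            for s, m in metrics.items():
                rows.append(
                    {
                        "config": config_id,
                        "grid_value": float(g),
                        "seed": seed,
                        "permutation": perm,
                        "split": s,
                        "accuracy": m.accuracy,
                        "auc": m.auc,
                        "selection_rate": sel,
                        "degenerate": degenerate,
                    }
                )
    return ValidationCurve(
        config_id=config_id,
        sweep_name=sweep_name,
        grid=grid,
        records=pd.DataFrame(rows),
        models=models,
        masks=masks,
    )


def aggregate_average_cv(curve: ValidationCurve) -> pd.DataFrame:
    """Average cross-validation: per grid point and split, the mean over
    permutations and the standard deviation of the mean."""
    rec = curve.records
    n = rec.groupby(["grid_value", "split"])["accuracy"].count().iloc[0]
    if n < 2:
        raise ValueError("average cross-validation needs >= 2 permutations")

    def sdom(x):
        return x.std(ddof=1) / np.sqrt(len(x))

    agg = rec.groupby(["grid_value", "split"]).agg(
        accuracy_mean=("accuracy", "mean"),
        accuracy_sdom=("accuracy", sdom),
        auc_mean=("auc", "mean"),
        auc_sdom=("auc", sdom),
        selection_rate_mean=("selection_rate", "mean"),
    )
    return agg.reset_index()


def aggregate_classical_cv(curve: ValidationCurve) -> dict:
    """Classical cross-validation: test metrics of the permutation/grid point
    with the highest validation accuracy (ties broken by higher validation
    AUC, then lower grid value).  Never inspects test metrics."""
    rec = curve.records
    val = rec[rec["split"] == "val"].copy()
    val = val.sort_values(
        by=["accuracy", "auc", "grid_value"], ascending=[False, False, True], kind="stable"
    )
    best = val.iloc[0]
    sel = rec[
        (rec["split"] == "test")
        & (rec["seed"] == best["seed"])
        & (rec["grid_value"] == best["grid_value"])
    ].iloc[0]
    return {
        "grid_value": float(best["grid_value"]),
        "seed": int(best["seed"]),
        "test_accuracy": float(sel["accuracy"]),
        "test_auc": float(sel["auc"]),
        "val_accuracy": float(best["accuracy"]),
        "val_auc": float(best["auc"]),
    }


def performance_enhancement(acc_model: float, acc_reference: float) -> float:
    """PE = model accuracy minus reference accuracy, in percentage points;
    negative PE means the model underperforms the reference."""
    return acc_model - acc_reference


def dice(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1 by convention."""
    a, b = mask_a.astype_bool(), mask_b.astype_bool()
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
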