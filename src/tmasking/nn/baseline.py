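"""Mean-intensity linear baseline.

Replaces the CNN with a linear decision rule on a single scalar feature: the
mean intensity of a subject's volume over the active mask voxels.  This
isolates the contribution of the statistical mask itself, without any learned
spatial filters.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression

from ..cohort import BinaryMask, VolumeStack

__all__ = ["MeanIntensityLinear", "linear_baseline"]


class MeanIntensityLinear:
    """Single-feature logistic classifier over the mean masked intensity."""

    def __init__(self, mask: BinaryMask):
        if mask.n_active == 0:
            raise ValueError("no features: the mask is empty")
        self.mask = mask
        self._clf = LogisticRegression()
        self._fallback_p: float | None = None

    def features(self, stack: VolumeStack) -> np.ndarray:
        sel = self.mask.astype_bool()
        return stack.volumes[:, sel].mean(axis=1, keepdims=True)

    def fit(self, train_stack: VolumeStack) -> "MeanIntensityLinear":
        f = self.features(train_stack)
        y = train_stack.labels
        if np.ptp(f) == 0:
            # uninformative feature: fall back to the training base rate
            self._fallback_p = float(np.mean(y))
            return self
        self._clf.fit(f, y)
        return self

    def predict_proba(self, stack: VolumeStack) -> np.ndarray:
        if self._fallback_p is not None:
            return np.full(len(stack), self._fallback_p)
        return self._clf.predict_proba(self.features(stack))[:, 1]

    @property
    def decision_boundary(self) -> float:
        """Feature value at which the predicted probability is 0.5."""
        if self._fallback_p is not None:
            return np.nan
        return float(-self._clf.intercept_[0] / self._clf.coef_[0, 0])


def linear_baseline(train_masked: VolumeStack, mask: BinaryMask) -> MeanIntensityLinear:
    """Fit the mean-intensity linear classifier on (already masked) training
    volumes; exposes the same ``predict_proba`` surface as the CNN wrapper."""
    return MeanIntensityLinear(mask).fit(train_masked)
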