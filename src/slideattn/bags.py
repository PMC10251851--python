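"""Per-slide instance-feature bags, the unit of weakly-supervised training.

A bag collects the feature vectors of all patches tiled from one slide,
together with their base-level pixel coordinates and the slide-level binary
label (lymph-node metastasis status). Supervision exists only at the bag
level; instance (patch) labels are unobserved in real data. Synthetic bags
additionally carry ground-truth witness flags for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FeatureBag:
    """Instance features for one slide.

    Parameters
    ----------
    slide_id, patient_id : str
        Provenance identifiers; several slides may share a patient.
    label : int
        Slide-level binary label (1 = metastasis present).
    features : ndarray of shape (n_instances, dim)
        One row per patch, finite values only.
    coords : ndarray of shape (n_instances, 2)
        (x, y) base-level pixel coordinates aligned with feature rows.
    witness : ndarray of bool, optional
        Ground-truth positive-instance flags; only synthetic bags have them.
    """

    slide_id: str
    patient_id: str
    label: int
    features: np.ndarray
    coords: np.ndarray = None
    witness: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        if self.coords is None:
            self.coords = np.zeros((self.features.shape[0], 2), dtype=np.int64)
        self.coords = np.asarray(self.coords)
        if self.coords.shape != (self.features.shape[0], 2):
            raise ValueError("coords must align with feature rows")
        if self.label not in (0, 1):
            raise ValueError("label must be binary")
        if self.witness is not None:
            self.witness = np.asarray(self.witness, dtype=bool)
            if self.witness.shape != (self.features.shape[0],):
                raise ValueError("witness flags must align with feature rows")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]
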