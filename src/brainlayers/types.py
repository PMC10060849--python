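"""Core data containers shared across the pipeline.

A cohort is a list of :class:`RoiTimeSeries` (one per subject).  Each network
layer built from a subject is a :class:`ConnectivityMatrix`; the strict upper
triangles of all subjects' matrices for one layer stack into an
:class:`EdgeFeatureTable`, the subjects × edges matrix on which feature
selection and classification operate.

Edge ordering is fixed package-wide: row-major strict upper triangle with
0-based ROI indices, i.e. (0,1), (0,2), …, (0,N−1), (1,2), …, (N−2,N−1).
Fused feature vectors and reported discriminative edges depend on this order,
so it is part of the public contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Layer = Literal["LOFC", "tHOFC", "aHOFC"]
LAYERS: tuple[Layer, ...] = ("LOFC", "tHOFC", "aHOFC")

Label = Literal["patient", "control"]
LABELS: tuple[Label, ...] = ("patient", "control")

#: absolute tolerance used everywhere a matrix is checked for symmetry
SYMMETRY_ATOL = 1e-8


def n_edges(n_rois: int) -> int:
    """Number of strict upper-triangle edges, N(N−1)/2."""
    return n_rois * (n_rois - 1) // 2


def edge_index_pairs(n_rois: int) -> list[tuple[int, int]]:
    """All (i, j) ROI pairs with i < j in row-major upper-triangle order."""
    iu, ju = np.triu_indices(n_rois, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def pair_to_edge(i: int, j: int, n_rois: int) -> int:
    """Vectorized edge index of the ROI pair (i, j), i < j, row-major order."""
    if not (0 <= i < j < n_rois):
        raise ValueError(f"need 0 <= i < j < n_rois, got ({i}, {j}) with n_rois={n_rois}")
    return i * n_rois - i * (i + 1) // 2 + (j - i - 1)


@dataclass
class RoiTimeSeries:
    """One subject's ROI-averaged time series with phenotype metadata.

    ``data`` is T×N (timepoints × regions) in arbitrary signal units.
    Pearson correlations need T ≥ 3 and no constant column; the synthetic
    generator guarantees this and the readers validate it.
    """

    subject_id: str
    site_id: str
    label: Label
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"{self.subject_id}: time series must be 2-D (T×N)")
        t, n = self.data.shape
        if t < 3 or n < 3:
            raise ValueError(
                f"{self.subject_id}: need T >= 3 and N >= 3, got T={t}, N={n}"
            )
        if self.label not in LABELS:
            raise ValueError(f"{self.subject_id}: label must be one of {LABELS}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def zero_variance_rois(self) -> list[int]:
        """Indices of constant (zero-variance) columns; correlations are undefined there."""
        return np.flatnonzero(np.ptp(self.data, axis=0) == 0.0).tolist()


@dataclass
class ConnectivityMatrix:
    """A subject's N×N weighted network for one layer.

    Entries are correlation-like weights in [−1, 1].  All three layers are
    symmetric (aHOFC after its (W + W′)/2 symmetrization); the diagonal is a
    convention (1 for LOFC/tHOFC) and never enters the feature vector.
    """

    subject_id: str
    layer: Layer
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"{self.subject_id}: connectivity matrix must be square")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeFeatureTable:
    """Subjects × edges feature matrix for one layer.

    ``features[s, e]`` is subject ``subjects[s]``'s weight at the ROI pair
    ``edge_index[e]``; ``edge_index`` covers the strict upper triangle in
    row-major order, so E = N(N−1)/2.
    """

    layer: Layer
    subjects: list[str]
    features: np.ndarray
    edge_index: list[tuple[int, int]] = field(repr=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (subjects × edges)")
        if self.features.shape[0] != len(self.subjects):
            raise ValueError("row count does not match subject list")
        if self.features.shape[1] != len(self.edge_index):
            raise ValueError("column count does not match edge index")

    @property
    def n_edges(self) -> int:
        return self.features.shape[1]


def labels_to_binary(labels: Sequence[str]) -> np.ndarray:
    """Encode diagnosis labels as 1 (patient) / 0 (control)."""
    out = np.empty(len(labels), dtype=int)
    for k, lab in enumerate(labels):
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
        out[k] = 1 if lab == "patient" else 0
    return out
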