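"""Edgewise feature selection and multi-layer feature fusion.

Edges are screened one at a time with a two-sided two-sample t-test
(patients vs controls) on the *training* subjects of a fold; edges with
p below the threshold (0.01 or 0.05 in the reference protocol) survive.
Raw p-values are thresholded deliberately — no multiple-testing correction —
mirroring the edge-screening convention of the protocol this pipeline
implements.  Selected feature blocks from the three layers are concatenated
(LOFC, tHOFC, aHOFC order) into the multi-layer feature vector.

Features are z-scored with training-fold statistics before classification;
the :class:`Standardizer` is stored with the fold's model for test-time reuse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import EdgeFeatureTable, Layer

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "FusedFeatures",
    "Standardizer",
    "edgewise_ttest",
    "select_edges",
    "fuse",
    "stable_edges",
]


@dataclass
class SelectionResult:
    """Per-edge p-values and the surviving edge set for one layer and fold."""

    layer: Layer
    p_values: np.ndarray
    selected: list[int]
    threshold: float
    fold_id: str = ""

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if np.any((self.p_values < 0) | (self.p_values > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        if self.selected != sorted(self.selected):
            raise ValueError("selected edge indices must be ascending")


@dataclass
class FusedFeatures:
    """Concatenated selected features with per-column provenance.

    ``provenance[k]`` is the (layer, edge index) the k-th column came from,
    so any classifier weight can be traced back to an ROI pair.
    """

    subjects: list[str]
    matrix: np.ndarray
    provenance: list[tuple[Layer, int]]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.subjects), len(self.provenance)):
            raise ValueError("fused matrix shape does not match subjects/provenance")


def edgewise_ttest(
    table: EdgeFeatureTable, labels: np.ndarray, *, welch: bool = False
) -> np.ndarray:
    """Two-sided two-sample t-test p-value per edge, patients vs controls.

    ``labels`` is the 1/0 (patient/control) vector aligned with the table's
    subject order.  Pooled-variance (Student) by default; ``welch=True``
    switches to the unequal-variance form.  Edges with zero pooled variance
    are degenerate and get p = 1 (never selected).
    """
    labels = np.asarray(labels)
    if labels.shape != (len(table.subjects),):
        raise ValueError("labels do not align with the feature table")
    a = table.features[labels == 1]
    b = table.features[labels == 0]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"both groups need >= 2 subjects (got {len(a)} patients, {len(b)} controls)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    p = np.asarray(p, dtype=float)
    n_degen = int(np.isnan(p).sum())
    if n_degen:
        logger.warning("%d edges had zero pooled variance; assigned p = 1", n_degen)
        p = np.nan_to_num(p, nan=1.0)
    return p


def select_edges(
    p_values: np.ndarray, threshold: float, *, layer: Layer = "LOFC", fold_id: str = ""
) -> SelectionResult:
    """Edges with p strictly below the threshold, ascending by edge index.

    An empty selection is legal and propagates; classifiers refuse to train
    on zero features with an explicit message.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    p_values = np.asarray(p_values, dtype=float)
    selected = np.flatnonzero(p_values < threshold).tolist()
    return SelectionResult(layer, p_values, selected, threshold, fold_id)


def fuse(
    tables: dict[str, EdgeFeatureTable],
    selections: dict[str, SelectionResult],
    layer_order: tuple[str, ...] = ("LOFC", "tHOFC", "aHOFC"),
) -> FusedFeatures:
    """Concatenate each layer's selected columns into the multi-layer feature.

    Layers appear in the fixed order LOFC, tHOFC, aHOFC (those present);
    a single-layer run is the degenerate one-block case.
    """
    present = [lay for lay in layer_order if lay in tables]
    if not present:
        raise ValueError("no layers to fuse")
    subjects = tables[present[0]].subjects
    for lay in present:
        if tables[lay].subjects != subjects:
            raise ValueError(f"subject order mismatch in layer {lay}")
        if lay not in selections:
            raise ValueError(f"missing selection for layer {lay}")
    blocks: list[np.ndarray] = []
    provenance: list[tuple[Layer, int]] = []
    for lay in present:
        sel = selections[lay].selected
        blocks.append(tables[lay].features[:, sel])
        provenance.extend((lay, e) for e in sel)  # type: ignore[misc]
    matrix = (
        np.hstack(blocks) if provenance else np.empty((len(subjects), 0))
    )
    return FusedFeatures(list(subjects), matrix, provenance)


def stable_edges(selections: list[SelectionResult]) -> set[int]:
    """Edges selected in *every* fold of one layer (set intersection)."""
    if len(selections) < 2:
        raise ValueError("stability needs at least 2 folds")
    out = set(selections[0].selected)
    for sel in selections[1:]:
        out &= set(sel.selected)
    return out


@dataclass
class Standardizer:
    """Per-feature z-scoring with training-fold statistics."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        x = np.asarray(x, dtype=float)
        sd = x.std(axis=0, ddof=0)
        return cls(mean=x.mean(axis=0), sd=np.where(sd == 0.0, 1.0, sd))

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"feature width {x.shape[1]} does not match fitted width {self.mean.shape[0]}"
            )
        return (x - self.mean) / self.sd
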