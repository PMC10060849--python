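"""Construction of the three functional-connectivity layers.

LOFC
    Low-order functional connectivity: the Pearson correlation between two
    ROIs' time series.  The classical correlation connectome.
tHOFC
    Topographical high-order FC: for a pair (i, j), the Pearson correlation
    between the two ROIs' LOFC *profiles* — their rows of the LOFC matrix,
    restricted to the other regions k ∉ {i, j}.  Two regions are strongly
    tHOFC-connected when they connect to the rest of the brain in the same
    pattern, even if their raw signals are uncorrelated.
aHOFC
    Associated high-order FC: the correlation between region i's tHOFC
    profile and region j's LOFC profile over k ∉ {i, j}.  The raw matrix is
    asymmetric; it is symmetrized as W ← (W + W′)/2.

All three are computed in closed form from restricted sums (no per-pair
Python loops), so a 116-ROI subject takes milliseconds.  Degenerate profiles
(zero variance after excluding i and j) yield an entry of 0 with a logged
warning — undefined correlation is treated as absent connectivity so batch
runs stay alive.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    SYMMETRY_ATOL,
    ConnectivityMatrix,
    EdgeFeatureTable,
    RoiTimeSeries,
    edge_index_pairs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "compute_lofc",
    "compute_thofc",
    "compute_ahofc",
    "compute_all_layers",
    "vectorize_upper",
    "devectorize",
    "build_feature_tables",
]


def compute_lofc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson-correlation network of one subject's ROI time series."""
    if ts.n_timepoints < 3:
        raise ValueError(f"{ts.subject_id}: need at least 3 timepoints for correlation")
    dead = ts.zero_variance_rois()
    if dead:
        raise ValueError(
            f"{ts.subject_id}: zero-variance ROI(s) {dead}; Pearson correlation undefined"
        )
    w = np.corrcoef(ts.data, rowvar=False)
    np.clip(w, -1.0, 1.0, out=w)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return ConnectivityMatrix(ts.subject_id, "LOFC", w)


def _restricted_profile_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Correlation of a's row-i profile with b's row-j profile over k ∉ {i, j}.

    For every ordered pair (i, j), i ≠ j, computes the Pearson correlation of
    (a[i, k]) and (b[j, k]) over the N−2 indices k ∉ {i, j}, via restricted
    sums so the whole matrix costs one matrix product.  Entries with a
    zero-variance profile are set to 0.
    """
    n = a.shape[0]
    m = n - 2  # profile length after excluding i and j
    sa = a.sum(axis=1)
    sb = b.sum(axis=1)
    qa = (a * a).sum(axis=1)
    qb = (b * b).sum(axis=1)
    cross = a @ b.T  # cross[i, j] = Σ_k a[i,k] b[j,k]

    # restricted sums: drop k = i and k = j from each statistic
    sa_r = sa[:, None] - np.diag(a)[:, None] - a  # sa_r[i, j] = Σ_{k∉{i,j}} a[i,k]
    sb_r = sb[None, :] - np.diag(b)[None, :] - b.T
    qa_r = qa[:, None] - np.diag(a)[:, None] ** 2 - a**2
    qb_r = qb[None, :] - np.diag(b)[None, :] ** 2 - (b.T) ** 2
    cross_r = cross - np.diag(a)[:, None] * b - a * np.diag(b)[None, :]

    num = cross_r - sa_r * sb_r / m
    var_a = qa_r - sa_r**2 / m
    var_b = qb_r - sb_r**2 / m
    # numerical negatives from cancellation are zero variance
    var_a = np.maximum(var_a, 0.0)
    var_b = np.maximum(var_b, 0.0)
    den = np.sqrt(var_a * var_b)

    degenerate = den <= m * 1e-14 * np.maximum(np.abs(qa_r), np.abs(qb_r)).clip(min=1.0)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=~degenerate)
    np.clip(out, -1.0, 1.0, out=out)
    off_diag = ~np.eye(n, dtype=bool)  # the diagonal is overwritten by callers
    n_degen = int((degenerate & off_diag).sum())
    if n_degen > 0:
        logger.warning(
            "%d high-order entries had zero-variance profiles; set to 0", n_degen
        )
    return out


def compute_thofc(lofc: ConnectivityMatrix) -> ConnectivityMatrix:
    """Topographical high-order network from a subject's LOFC matrix.

    tHOFC[i, j] correlates the LOFC rows of i and j over regions k ∉ {i, j}.
    The diagonal is set to 1 by convention (it never enters the features).
    """
    if lofc.layer != "LOFC":
        raise ValueError(f"expected a LOFC matrix, got {lofc.layer}")
    n = lofc.n_rois
    if n < 4:
        raise ValueError("tHOFC needs at least 4 ROIs (profiles of length >= 2)")
    w = lofc.values
    out = _restricted_profile_corr(w, w)
    out = (out + out.T) / 2.0  # symmetric analytically; enforce exactly
    np.fill_diagonal(out, 1.0)
    return ConnectivityMatrix(lofc.subject_id, "tHOFC", out)


def compute_ahofc(
    thofc: ConnectivityMatrix, lofc: ConnectivityMatrix
) -> ConnectivityMatrix:
    """Associated high-order network: tHOFC profile of i vs LOFC profile of j.

    The raw matrix A (A[i, j] over k ∉ {i, j}) is asymmetric; the returned
    matrix is (A + A′)/2.
    """
    if thofc.layer != "tHOFC" or lofc.layer != "LOFC":
        raise ValueError("compute_ahofc needs (tHOFC, LOFC) inputs in that order")
    if thofc.subject_id != lofc.subject_id:
        raise ValueError(
            f"subject mismatch: {thofc.subject_id!r} vs {lofc.subject_id!r}"
        )
    if thofc.n_rois != lofc.n_rois:
        raise ValueError("ROI count mismatch between tHOFC and LOFC")
    n = lofc.n_rois
    if n < 4:
        raise ValueError("aHOFC needs at least 4 ROIs (profiles of length >= 2)")
    raw = _restricted_profile_corr(thofc.values, lofc.values)
    # diagonal: correlation of i's two profiles over k ≠ i (length N−1)
    for i in range(n):
        keep = np.arange(n) != i
        a = thofc.values[i, keep]
        b = lofc.values[i, keep]
        sa, sb = a.std(), b.std()
        raw[i, i] = 0.0 if sa == 0.0 or sb == 0.0 else float(np.corrcoef(a, b)[0, 1])
    sym = (raw + raw.T) / 2.0
    np.clip(sym, -1.0, 1.0, out=sym)
    return ConnectivityMatrix(lofc.subject_id, "aHOFC", sym)


def compute_all_layers(ts: RoiTimeSeries) -> dict[str, ConnectivityMatrix]:
    """All three layers for one subject, keyed by layer name."""
    lofc = compute_lofc(ts)
    thofc = compute_thofc(lofc)
    ahofc = compute_ahofc(thofc, lofc)
    return {"LOFC": lofc, "tHOFC": thofc, "aHOFC": ahofc}


def vectorize_upper(m: ConnectivityMatrix) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix as a length-N(N−1)/2 vector.

    Row-major order; a 116-ROI matrix yields 6670 features.  Raises if the
    matrix is asymmetric beyond the package symmetry tolerance.
    """
    w = m.values
    if not np.allclose(w, w.T, atol=SYMMETRY_ATOL, rtol=0.0):
        raise ValueError(
            f"{m.subject_id}: {m.layer} matrix asymmetric beyond {SYMMETRY_ATOL}"
        )
    iu, ju = np.triu_indices(m.n_rois, k=1)
    return w[iu, ju].copy()


def devectorize(vec: np.ndarray, n_rois: int, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` (up to the diagonal convention)."""
    vec = np.asarray(vec, dtype=float)
    expected = n_rois * (n_rois - 1) // 2
    if vec.shape != (expected,):
        raise ValueError(f"expected vector of length {expected}, got {vec.shape}")
    out = np.full((n_rois, n_rois), diagonal)
    iu, ju = np.triu_indices(n_rois, k=1)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return out


def build_feature_tables(
    cohort: list[RoiTimeSeries], layers: tuple[str, ...] = ("LOFC", "tHOFC", "aHOFC")
) -> dict[str, EdgeFeatureTable]:
    """Networks + vectorization for a whole cohort, one table per layer.

    Matrices are computed once per subject and shared between the layers that
    need them, so this is the single entry point the cross-validation loop
    uses.
    """
    if not cohort:
        raise ValueError("empty cohort")
    n = cohort[0].n_rois
    if any(ts.n_rois != n for ts in cohort):
        raise ValueError("all subjects must share the same ROI count")
    pairs = edge_index_pairs(n)
    rows: dict[str, list[np.ndarray]] = {layer: [] for layer in layers}
    for ts in cohort:
        mats = compute_all_layers(ts) if set(layers) != {"LOFC"} else {
            "LOFC": compute_lofc(ts)
        }
        for layer in layers:
            rows[layer].append(vectorize_upper(mats[layer]))
    subjects = [ts.subject_id for ts in cohort]
    return {
        layer: EdgeFeatureTable(layer, subjects, np.vstack(rows[layer]), list(pairs))
        for layer in layers
    }
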