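"""Network construction: correlation layers, their oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainlayers import (
    ConnectivityMatrix,
    RoiTimeSeries,
    compute_ahofc,
    compute_all_layers,
    compute_lofc,
    compute_thofc,
    devectorize,
    vectorize_upper,
)
from conftest import random_symmetric_correlationlike
from oracles import ahofc_longhand, lofc_longhand, thofc_longhand


def _ts(data, subject="sub", site="s1", label="control"):
    return RoiTimeSeries(subject, site, label, np.asarray(data, float))


class TestLofc:
    def test_identical_and_anticorrelated_columns(self, rng):
        base = rng.normal(size=8)
        data = np.column_stack([base, base, -base + 3.0])
        w = compute_lofc(_ts(data)).values
        assert w[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert w[0, 2] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(np.diag(w), 1.0)

    def test_small_integer_fixture_matches_longhand_sums(self):
        data = np.array(
            [[1, 2, 0], [3, 1, 2], [2, 4, 1], [5, 3, 3], [4, 2, 2], [6, 5, 4]],
            dtype=float,
        )
        w = compute_lofc(_ts(data)).values
        assert np.abs(w - lofc_longhand(data)).max() < 1e-12

    def test_zero_variance_column_names_the_roi(self, rng):
        data = rng.normal(size=(10, 4))
        data[:, 2] = 7.0
        with pytest.raises(ValueError, match=r"zero-variance ROI.*\[2\]"):
            compute_lofc(_ts(data))

    def test_too_few_timepoints_rejected(self, rng):
        with pytest.raises(ValueError):
            RoiTimeSeries("s", "x", "control", rng.normal(size=(2, 5)))


class TestThofc:
    def test_constant_profiles_take_degenerate_branch(self):
        n = 6
        w = np.full((n, n), 0.3)
        np.fill_diagonal(w, 1.0)
        th = compute_thofc(ConnectivityMatrix("s", "LOFC", w)).values
        off = th[~np.eye(n, dtype=bool)]
        assert np.all(off == 0.0)

    def test_affine_profiles_give_unit_correlation(self):
        # rows 0 and 1 are exact positive-slope affine copies after removing
        # entries 0 and 1
        n = 6
        w = random_symmetric_correlationlike(n, np.random.default_rng(3))
        rest = list(range(2, n))
        w[1, rest] = 2.0 * w[0, rest] + 0.1
        w[rest, 1] = w[1, rest]
        th = compute_thofc(ConnectivityMatrix("s", "LOFC", w)).values
        assert th[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_needs_at_least_four_rois(self):
        w = np.eye(3)
        with pytest.raises(ValueError):
            compute_thofc(ConnectivityMatrix("s", "LOFC", w))

    def test_differs_from_lofc_on_random_fixtures(self, rng):
        data = rng.normal(size=(40, 8))
        lofc = compute_lofc(_ts(data))
        th = compute_thofc(lofc)
        assert np.abs(th.values - lofc.values).max() > 0.0


class TestAhofc:
    def test_symmetrization_is_fixed_point_on_symmetric_raw(self, rng):
        # thofc == lofc makes the raw cross-layer matrix equal the tHOFC of
        # lofc, so the output is that matrix symmetrized
        w = random_symmetric_correlationlike(6, rng)
        lofc = ConnectivityMatrix("s", "LOFC", w)
        th_of_w = thofc_longhand(w)
        fake_th = ConnectivityMatrix("s", "tHOFC", w.copy())
        out = compute_ahofc(fake_th, lofc).values
        expected = (th_of_w + th_of_w.T) / 2.0
        off = ~np.eye(6, dtype=bool)
        assert np.abs(out[off] - expected[off]).max() < 1e-12

    def test_subject_mismatch_rejected(self, rng):
        w = random_symmetric_correlationlike(6, rng)
        with pytest.raises(ValueError, match="mismatch"):
            compute_ahofc(
                ConnectivityMatrix("a", "tHOFC", w), ConnectivityMatrix("b", "LOFC", w)
            )


@pytest.mark.parametrize("n_rois", [5, 6, 8])
@pytest.mark.parametrize("seed", [0, 1])
def test_all_layers_match_longhand_oracles(n_rois, seed):
    """LOFC/tHOFC/aHOFC equal their explicit profile-construction oracles."""
    rng = np.random.default_rng(seed)
    ts = _ts(rng.normal(size=(30, n_rois)))
    mats = compute_all_layers(ts)
    off = ~np.eye(n_rois, dtype=bool)

    lofc_ref = lofc_longhand(ts.data)
    assert np.abs(mats["LOFC"].values - lofc_ref).max() < 1e-12
    th_ref = thofc_longhand(lofc_ref)
    th_ref_sym = (th_ref + th_ref.T) / 2.0
    assert np.abs(mats["tHOFC"].values[off] - th_ref_sym[off]).max() < 1e-12
    ah_ref = ahofc_longhand(mats["tHOFC"].values, lofc_ref)
    assert np.abs(mats["aHOFC"].values[off] - ah_ref[off]).max() < 1e-12


def test_all_entries_bounded(rng):
    for _ in range(5):
        ts = _ts(rng.normal(size=(25, 7)))
        for m in compute_all_layers(ts).values():
            assert m.values.min() >= -1.0 and m.values.max() <= 1.0


def test_roi_permutation_equivariance(rng):
    """Relabeling ROIs permutes every layer conjugately (P W P')."""
    n = 7
    data = rng.normal(size=(30, n))
    perm = rng.permutation(n)
    mats = compute_all_layers(_ts(data))
    mats_p = compute_all_layers(_ts(data[:, perm]))
    for layer in ("LOFC", "tHOFC", "aHOFC"):
        conj = mats[layer].values[np.ix_(perm, perm)]
        assert np.allclose(mats_p[layer].values, conj, atol=1e-10)


class TestVectorize:
    def test_aal_size_gives_6670_features(self):
        w = np.zeros((116, 116))
        vec = vectorize_upper(ConnectivityMatrix("s", "LOFC", w))
        assert vec.shape == (6670,)

    def test_smallest_case_ordering(self):
        w = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        vec = vectorize_upper(ConnectivityMatrix("s", "LOFC", w))
        assert vec.tolist() == [1.0, 2.0, 3.0]

    def test_asymmetric_matrix_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = 1e-3
        with pytest.raises(ValueError, match="asymmetric"):
            vectorize_upper(ConnectivityMatrix("s", "LOFC", w))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(3, 12), seed=st.integers(0, 10_000))
    def test_devectorize_round_trip(self, n, seed):
        w = random_symmetric_correlationlike(n, np.random.default_rng(seed))
        vec = vectorize_upper(ConnectivityMatrix("s", "LOFC", w))
        back = devectorize(vec, n, diagonal=1.0)
        assert np.array_equal(back, w)
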