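import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import convolve_trains

from erpdecon.design import build_design
from erpdecon.formula import ModelSpec
from erpdecon.timeexpand import (
    TemporalBasis,
    add_continuous_covariate,
    assemble,
    basis_transform,
    local_window,
    onsets_to_samples,
    time_expand,
)


def simple_design(n, columns=None):
    events = pd.DataFrame({"onset": np.linspace(0, 1, n), "type": "stim"})
    if columns is not None:
        for name, vals in columns.items():
            events[name] = vals
    formula = "y ~ 1" + "".join(f" + {c}" for c in (columns or {}))
    return build_design(events, ModelSpec(formula, window=(0, 0.5)))


# ---------------------------------------------------------------------------
# onset rounding and window grids
# ---------------------------------------------------------------------------


def test_onsets_round_half_to_even():
    srate = 10.0
    # 0.25 s * 10 = 2.5 -> 2 ; 0.35 s * 10 = 3.5 -> 4
    assert onsets_to_samples([0.25, 0.35], srate).tolist() == [2, 4]


def test_onsets_outside_recording_are_excluded_with_warning():
    with pytest.warns(UserWarning, match="outside"):
        samples, keep = onsets_to_samples([-0.5, 0.1, 9.9], 10.0, n_samples=50)
    assert samples.tolist() == [1]
    assert keep.tolist() == [False, True, False]


def test_local_window_is_inclusive_of_both_endpoints():
    grid = local_window(-0.1, 0.3, 100.0)
    assert grid[0] == -10 and grid[-1] == 30
    assert len(grid) == 41


def test_local_window_rejects_empty_or_reversed():
    with pytest.raises(ValueError):
        local_window(0.3, 0.1, 100.0)
    with pytest.raises(ValueError):
        local_window(0.0, 0.001, 100.0)  # rounds to < 2 samples


# ---------------------------------------------------------------------------
# temporal bases
# ---------------------------------------------------------------------------


def test_stick_basis_is_identity():
    assert np.array_equal(basis_transform(TemporalBasis("stick"), 7), np.eye(7))


def test_time_spline_basis_partitions_unity():
    T = basis_transform(TemporalBasis("spline", n_basis=8), 50)
    assert T.shape == (50, 8)
    assert np.abs(T.sum(axis=1) - 1).max() < 1e-9


def test_fourier_columns_are_orthonormal():
    T = basis_transform(TemporalBasis("fourier", n_harmonics=4), 60)
    assert T.shape == (60, 9)
    gram = T.T @ T
    assert np.abs(gram - np.eye(9)).max() < 1e-9


def test_fourier_spans_only_low_frequencies():
    K, n = 3, 64
    T = basis_transform(TemporalBasis("fourier", n_harmonics=K), n)
    # any column's spectrum is zero above harmonic K
    spectra = np.abs(np.fft.rfft(T, axis=0))
    assert spectra[K + 1 :, :].max() < 1e-9 * spectra.max()


def test_basis_wider_than_window_rejected():
    with pytest.raises(ValueError, match="exceeds"):
        basis_transform(TemporalBasis("spline", n_basis=10), 8)


def test_temporal_basis_parameter_validation():
    with pytest.raises(ValueError):
        TemporalBasis("spline", n_basis=3)
    with pytest.raises(ValueError):
        TemporalBasis("fourier")
    with pytest.raises(ValueError):
        TemporalBasis("wavelet")


# ---------------------------------------------------------------------------
# the expansion itself
# ---------------------------------------------------------------------------


def test_single_event_places_its_window_on_the_diagonal():
    design = simple_design(1)
    window = np.arange(0, 5)
    expanded = time_expand(design, [10], window, TemporalBasis("stick"), 30, "stim", 100.0)
    dense = expanded.X.toarray()
    assert dense.shape == (30, 5)
    for k in range(5):
        col = np.zeros(30)
        col[10 + k] = 1.0
        assert np.array_equal(dense[:, k], col)


def test_overlapping_windows_sum_in_shared_cells():
    """Two events of one type, 3 samples apart, 5-sample window: rows in
    the overlap carry a one from each event in different columns, and a
    coincident duplicate event doubles every entry."""
    design = simple_design(2)
    window = np.arange(0, 5)
    expanded = time_expand(design, [10, 13], window, TemporalBasis("stick"), 30, "stim", 100.0)
    dense = expanded.X.toarray()
    # row 13 = onset 10 + local 3 AND onset 13 + local 0 -> two entries
    assert dense[13].tolist() == [1, 0, 0, 1, 0]

    dup = time_expand(simple_design(2), [10, 10], window, TemporalBasis("stick"), 30, "stim", 100.0)
    assert np.array_equal(dup.X.toarray(), 2 * time_expand(
        simple_design(1), [10], window, TemporalBasis("stick"), 30, "stim", 100.0
    ).X.toarray())


def test_worked_overlap_example_row_25():
    """Events of type A at samples 21 and 25, one of type B at sample 22,
    stick basis over a 5-sample window starting at onset: row 25 holds
    exactly three nonzero entries — (A, local 4), (B, local 3), (A, local 0)."""
    window = np.arange(0, 5)
    a = time_expand(simple_design(2), [21, 25], window, TemporalBasis("stick"), 40, "A", 100.0)
    b = time_expand(simple_design(1), [22], window, TemporalBasis("stick"), 40, "B", 100.0)
    X = assemble([a, b], 100.0)
    row = X.X.toarray()[25]
    nz = np.nonzero(row)[0]
    assert len(nz) == 3
    refs = [X.colmap[i] for i in nz]
    got = {(r.event_type, r.basis_index) for r in refs}
    assert got == {("A", 4), ("A", 0), ("B", 3)}
    assert np.allclose(row[nz], 1.0)


def test_partial_windows_at_the_edges_are_truncated():
    design = simple_design(2)
    window = np.arange(-2, 3)
    expanded = time_expand(design, [0, 9], window, TemporalBasis("stick"), 10, "stim", 100.0)
    dense = expanded.X.toarray()
    # onset 0: local -2, -1 fall before the recording; onset 9: local +1, +2 after
    assert dense[:, 0].sum() == 1.0  # only the event at 9 contributes local -2
    assert dense[0, 2] == 1.0  # onset 0 at local 0
    assert dense[9, 2] == 1.0


def test_covariate_scales_the_stick_entries():
    design = simple_design(3, {"lum": [2.0, 5.0, -1.0]})
    window = np.arange(0, 3)
    expanded = time_expand(design, [0, 10, 20], window, TemporalBasis("stick"), 30, "stim", 100.0)
    dense = expanded.X.toarray()
    # columns 0-2 intercept, 3-5 lum
    assert dense[10, 3 + 0] == 5.0
    assert dense[21, 3 + 1] == -1.0
    assert dense[10, 0] == 1.0


def test_spline_temporal_basis_compresses_columns():
    design = simple_design(4)
    window = np.arange(0, 40)
    basis = TemporalBasis("spline", n_basis=6)
    expanded = time_expand(design, [0, 50, 100, 150], window, basis, 200, "stim", 100.0)
    assert expanded.n_columns == 6
    # reconstructing through the transform reproduces the stick version
    stick = time_expand(simple_design(4), [0, 50, 100, 150], window, TemporalBasis("stick"), 200, "stim", 100.0)
    T = expanded.blocks["stim"]["transform"]
    assert np.abs(expanded.X.toarray() - stick.X.toarray() @ T).max() < 1e-12


def test_underdetermined_expansion_warns():
    design = simple_design(1)
    with pytest.warns(UserWarning, match="underdetermined"):
        time_expand(design, [0], np.arange(0, 20), TemporalBasis("stick"), 10, "stim", 100.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_stick_expansion_reproduces_discrete_convolution(seed):
    """X_dc @ beta with per-local-sample beta equals the convolution of
    the event train with that kernel — the defining property."""
    rng = np.random.default_rng(seed)
    n_total = 200
    n_ev = int(rng.integers(1, 12))
    onsets = np.sort(rng.choice(n_total - 20, n_ev, replace=False))
    window = np.arange(0, int(rng.integers(2, 15)))
    kernel = rng.normal(size=len(window))
    design = simple_design(n_ev)
    expanded = time_expand(design, onsets, window, TemporalBasis("stick"), n_total, "stim", 100.0)
    train = np.zeros(n_total)
    np.add.at(train, onsets, 1.0)
    expected = convolve_trains([train], [kernel], n_total)
    got = expanded.X @ kernel
    assert np.abs(got - expected).max() < 1e-10


# ---------------------------------------------------------------------------
# assembly and covariate columns
# ---------------------------------------------------------------------------


def test_assemble_rejects_duplicate_event_types():
    design = simple_design(1)
    window = np.arange(0, 3)
    a = time_expand(design, [0], window, TemporalBasis("stick"), 10, "stim", 100.0)
    with pytest.raises(ValueError, match="duplicate"):
        assemble([a, a], 100.0)


def test_assemble_rejects_mismatched_row_counts():
    design = simple_design(1)
    window = np.arange(0, 3)
    a = time_expand(design, [0], window, TemporalBasis("stick"), 10, "A", 100.0)
    b = time_expand(design, [0], window, TemporalBasis("stick"), 12, "B", 100.0)
    with pytest.raises(ValueError, match="row counts"):
        assemble([a, b], 100.0)


def test_continuous_covariate_appends_one_dense_column():
    design = simple_design(1)
    a = time_expand(design, [0], np.arange(0, 3), TemporalBasis("stick"), 10, "stim", 100.0)
    sig = np.arange(10.0)
    out = add_continuous_covariate(a, sig, "pupil")
    assert out.n_columns == a.n_columns + 1
    assert np.array_equal(out.X.toarray()[:, -1], sig)
    assert out.colmap[-1].kind == "continuous_covariate"
    with pytest.raises(ValueError, match="length"):
        add_continuous_covariate(a, np.arange(9.0), "pupil")


def test_columns_for_filters_by_event_type_and_label():
    design = simple_design(1)
    window = np.arange(0, 4)
    a = time_expand(design, [0], window, TemporalBasis("stick"), 10, "A", 100.0)
    b = time_expand(design, [1], window, TemporalBasis("stick"), 10, "B", 100.0)
    X = assemble([a, b], 100.0)
    assert X.columns_for("A") == [0, 1, 2, 3]
    assert X.columns_for("B", "intercept") == [4, 5, 6, 7]


def test_save_round_trips_through_matrix_market(tmp_path):
    from scipy.io import mmread
    import json

    design = simple_design(2)
    expanded = time_expand(design, [3, 7], np.arange(0, 4), TemporalBasis("stick"), 15, "stim", 100.0)
    expanded.save(tmp_path / "X.mtx", tmp_path / "cols.json")
    back = mmread(tmp_path / "X.mtx").toarray()
    assert np.array_equal(back, expanded.X.toarray())
    meta = json.loads((tmp_path / "cols.json").read_text())
    assert meta["srate"] == 100.0
    assert len(meta["columns"]) == expanded.n_columns
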