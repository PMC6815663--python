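import numpy as np
import pandas as pd
import pytest

from oracles import cox_de_boor_basis

from erpdecon.design import (
    DegeneratePredictorError,
    SplineBasisSet,
    bspline_basis,
    build_design,
    cyclic_spline_basis,
    impute_missing,
    load_events,
    quantile_knots,
    tensor_spline_basis,
)
from erpdecon.formula import ModelSpec


# ---------------------------------------------------------------------------
# knots
# ---------------------------------------------------------------------------


def test_knot_count_law_for_every_size(rng):
    values = rng.uniform(0, 1, 500)
    for n_basis in range(4, 15):
        knots = quantile_knots(values, n_basis)
        assert len(knots) - 4 == n_basis
        assert np.all(np.diff(knots) >= 0)
        # clamped ends: boundary knots repeated 4 times
        assert np.allclose(knots[:4], knots[0])
        assert np.allclose(knots[-4:], knots[-1])


def test_knots_sit_on_empirical_quantiles(rng):
    values = rng.uniform(0, 1, 20000)
    knots = quantile_knots(values, 6)
    # 4 quantile points at levels 0, 1/3, 2/3, 1 of the observed values
    expected = np.quantile(values, np.linspace(0, 1, 4))
    assert np.allclose(knots[3:7], expected)
    assert knots[0] == values.min() and knots[-1] == values.max()


def test_constant_predictor_is_degenerate():
    with pytest.raises(DegeneratePredictorError):
        quantile_knots(np.ones(50), 5)


def test_too_small_basis_rejected(rng):
    with pytest.raises(ValueError):
        quantile_knots(rng.uniform(0, 1, 50), 3)


# ---------------------------------------------------------------------------
# B-spline evaluation
# ---------------------------------------------------------------------------


def test_partition_of_unity_and_locality(rng):
    values = rng.uniform(-3, 7, 300)
    knots = quantile_knots(values, 8)
    basis = bspline_basis(values, knots)
    assert basis.shape == (300, 8)
    assert np.abs(basis.sum(axis=1) - 1).max() < 1e-9
    assert (np.count_nonzero(basis, axis=1) <= 4).all()


def test_left_boundary_is_clamped(rng):
    knots = quantile_knots(rng.uniform(0, 1, 100), 5)
    row = bspline_basis([knots[0]], knots)[0]
    assert np.allclose(row, [1, 0, 0, 0, 0])
    row = bspline_basis([knots[-1]], knots)[0]
    assert np.allclose(row, [0, 0, 0, 0, 1])


def test_out_of_range_values_clamp_to_boundary(rng):
    knots = quantile_knots(rng.uniform(0, 1, 100), 5)
    inside = bspline_basis([knots[0], knots[-1]], knots)
    outside = bspline_basis([knots[0] - 10, knots[-1] + 10], knots)
    assert np.allclose(inside, outside)


def test_matches_cox_de_boor_oracle(rng):
    """Dual-route check: scipy-backed evaluation vs textbook recursion."""
    worst = 0.0
    for _ in range(100):
        values = rng.uniform(-5, 5, 60)
        n_basis = int(rng.integers(4, 10))
        knots = quantile_knots(values, n_basis)
        x = rng.uniform(knots[0], knots[-1], 40)
        x = np.append(x, [knots[0], knots[-1]])
        ours = bspline_basis(x, knots)
        oracle = cox_de_boor_basis(x, knots)
        worst = max(worst, np.abs(ours - oracle).max())
    assert worst < 1e-10


# ---------------------------------------------------------------------------
# cyclic splines
# ---------------------------------------------------------------------------


def test_cyclic_basis_is_periodic():
    lo, hi = 0.0, 360.0
    left = cyclic_spline_basis([lo], 5, lo, hi)
    right = cyclic_spline_basis([hi], 5, lo, hi)
    assert np.abs(left - right).max() < 1e-9


def test_cyclic_partition_of_unity(rng):
    vals = rng.uniform(-720, 720, 200)
    basis = cyclic_spline_basis(vals, 6, 0, 360)
    assert basis.shape == (200, 6)
    assert np.abs(basis.sum(axis=1) - 1).max() < 1e-9


def test_cyclic_shift_invariance():
    """Moving a point by one knot spacing rotates the basis columns."""
    n = 6
    h = 360.0 / n
    x = np.linspace(0, 360, 50, endpoint=False)
    base = cyclic_spline_basis(x, n, 0, 360)
    shifted = cyclic_spline_basis(x + h, n, 0, 360)
    assert np.abs(shifted - np.roll(base, 1, axis=1)).max() < 1e-9


def test_cyclic_needs_three_functions():
    with pytest.raises(ValueError):
        cyclic_spline_basis([0.0], 2, 0, 360)


# ---------------------------------------------------------------------------
# tensor splines
# ---------------------------------------------------------------------------


def test_tensor_column_count_is_squared(rng):
    a = rng.uniform(0, 1, 300)
    b = rng.uniform(0, 1, 300)
    for n in (4, 10):
        ba = bspline_basis(a, quantile_knots(a, n))
        bb = bspline_basis(b, quantile_knots(b, n))
        tensor = tensor_spline_basis(a, b, ba, bb)
        assert tensor.shape == (300, n**2)
        # product of two partitions of unity
        assert np.abs(tensor.sum(axis=1) - 1).max() < 1e-9


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------


def make_events(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "onset": np.sort(rng.uniform(0, 30, n)),
            "type": "stim",
            "cond": rng.choice(["a", "b", "c"], n),
            "is_face": rng.choice(["face", "house"], n),
            "luminance": rng.uniform(1, 20, n),
            "x": rng.uniform(0, 1, n),
        }
    )


def test_three_level_factor_treatment_coding():
    events = make_events()
    dm = build_design(events, ModelSpec("y ~ 1 + cat(cond)", window=(0, 0.5)))
    assert dm.n_columns == 3  # intercept + 2 indicators
    assert dm.column_labels == ["intercept", "cond[b]", "cond[c]"]
    assert dm.reference["cond"] == "a"  # alphabetical
    assert np.allclose(dm.values[:, 0], 1.0)


def test_reference_level_override():
    events = make_events()
    dm = build_design(
        events,
        ModelSpec(
            "y ~ 1 + cat(cond)", window=(0, 0.5), reference_levels={"cond": "c"}
        ),
    )
    assert dm.reference["cond"] == "c"
    assert dm.column_labels == ["intercept", "cond[a]", "cond[b]"]


def test_spline_term_loses_one_column_under_intercept():
    events = make_events()
    dm = build_design(events, ModelSpec("y ~ 1 + spl(x,5)", window=(0, 0.5)))
    assert dm.n_columns == 1 + 4
    # full design is full rank (identifiability restored)
    assert np.linalg.matrix_rank(dm.values) == 5


def test_two_condition_plus_covariate_model_has_three_columns():
    events = make_events()
    dm = build_design(
        events, ModelSpec("y ~ 1 + cat(is_face) + luminance", window=(0, 0.5))
    )
    assert dm.n_columns == 3


def test_treatment_and_effects_coding_span_the_same_space():
    events = make_events()
    treat = build_design(
        events, ModelSpec("y ~ 1 + cat(cond)", window=(0, 0.5), coding="treatment")
    ).values
    eff = build_design(
        events, ModelSpec("y ~ 1 + cat(cond)", window=(0, 0.5), coding="effects")
    ).values
    proj = lambda X: X @ np.linalg.pinv(X)
    assert np.abs(proj(treat) - proj(eff)).max() < 1e-9


def test_effects_coding_sums_to_zero_over_balanced_levels():
    events = make_events()
    dm = build_design(
        events, ModelSpec("y ~ 1 + cat(cond)", window=(0, 0.5), coding="effects")
    )
    col = dm.values[:, 1]
    # each level contributes +1, 0 or -1; the alphabetically last is -1
    last = events["cond"] == "c"
    assert np.all(col[last.to_numpy()] == -1.0)


def test_interaction_columns_are_products():
    events = make_events()
    dm = build_design(
        events, ModelSpec("y ~ 1 + cat(is_face)*luminance", window=(0, 0.5))
    )
    assert dm.column_labels == [
        "intercept",
        "is_face[house]",
        "luminance",
        "is_face[house]:luminance",
    ]
    assert np.allclose(dm.values[:, 3], dm.values[:, 1] * dm.values[:, 2])


def test_all_zero_column_warns_but_is_kept():
    events = make_events()
    events["zeros"] = 0.0
    with pytest.warns(UserWarning, match="all zeros"):
        dm = build_design(events, ModelSpec("y ~ 1 + zeros", window=(0, 0.5)))
    assert dm.n_columns == 2


def test_nan_in_design_is_rejected():
    events = make_events()
    events.loc[3, "luminance"] = np.nan
    with pytest.raises(ValueError, match="impute"):
        build_design(events, ModelSpec("y ~ 1 + luminance", window=(0, 0.5)))


def test_spline_basis_set_records_dropped_column():
    events = make_events()
    dm = build_design(events, ModelSpec("y ~ 1 + spl(x,6)", window=(0, 0.5)))
    bset = dm.spline_bases["spl(x,6)"]
    assert isinstance(bset, SplineBasisSet)
    assert bset.dropped is not None and 0 <= bset.dropped < 6
    # the dropped basis peaks near the median of x
    med = np.median(events["x"])
    peaks = bset.peak_locations()
    assert abs(peaks[bset.dropped] - med) == pytest.approx(
        np.min(np.abs(peaks - med)), abs=1e-12
    )


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def with_missing():
    return pd.DataFrame(
        {
            "onset": [0.1, 0.2, 0.3],
            "type": "stim",
            "x": [1.0, np.nan, 3.0],
        }
    )


@pytest.mark.parametrize("method", ["mean", "median"])
def test_statistic_imputation(method):
    out = impute_missing(with_missing(), method)
    assert out["x"].tolist() == [1.0, 2.0, 3.0]


def test_marginal_imputation_is_seeded_and_reproducible():
    a = impute_missing(with_missing(), "marginal", seed=7)
    b = impute_missing(with_missing(), "marginal", seed=7)
    pd.testing.assert_frame_equal(a, b)
    assert a.loc[1, "x"] in (1.0, 3.0)


def test_marginal_requires_seed():
    with pytest.raises(ValueError):
        impute_missing(with_missing(), "marginal")


def test_drop_removes_whole_event_with_warning():
    with pytest.warns(UserWarning, match="overlap"):
        out = impute_missing(with_missing(), "drop")
    assert len(out) == 2


def test_entirely_missing_column_cannot_be_imputed():
    events = with_missing()
    events["x"] = np.nan
    with pytest.raises(ValueError, match="entirely missing"):
        impute_missing(events, "mean")


def test_load_events_sorts_and_keeps_original_order(tmp_path):
    path = tmp_path / "events.tsv"
    pd.DataFrame(
        {"onset": [1.0, 0.2, 0.6], "type": ["a", "b", "a"], "x": [1, 2, 3]}
    ).to_csv(path, sep="\t", index=False)
    events = load_events(path)
    assert events["onset"].is_monotonic_increasing
    assert events["orig_index"].tolist() == [1, 2, 0]
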