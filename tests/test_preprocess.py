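"""Outlier rule and Z-RT standardization against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ema_rt.preprocess import (compute_iqr_bounds, filter_outliers,
                               preprocess, z_standardize)
from ema_rt.simulate import SimConfig, generate_cohort
from tests.conftest import toy_records


def brute_quartile(xs, q):
    """Linear-interpolation quantile computed from first principles."""
    xs = sorted(xs)
    pos = q * (len(xs) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


def test_zero_iqr_excludes_nothing():
    rec = toy_records([2, 2, 2, 2])
    (b,) = compute_iqr_bounds(rec)
    assert b.q1 == b.q3 == b.lower == b.upper == 2
    kept, removed = filter_outliers(rec, [b])
    assert len(kept) == 4 and removed.empty


def test_bound_formula():
    """q1=2, q3=6 must give lower 0 and upper 12."""
    # 8 evenly spread values with quartiles exactly at 2 and 6
    rec = toy_records([2, 2, 2, 2, 6, 6, 6, 6])
    (b,) = compute_iqr_bounds(rec)
    assert (b.q1, b.q3) == (2, 6)
    assert b.lower == 2 - 0.5 * 4 == 0
    assert b.upper == 6 + 1.5 * 4 == 12


def test_eight_point_sample_against_brute_force():
    rts = [1, 2, 3, 4, 5, 6, 7, 100]
    rec = toy_records(rts)
    (b,) = compute_iqr_bounds(rec)
    q1 = brute_quartile(rts, 0.25)
    q3 = brute_quartile(rts, 0.75)
    assert b.q1 == pytest.approx(q1)
    assert b.q3 == pytest.approx(q3)
    kept, removed = filter_outliers(rec, [b])
    expect_removed = {x for x in rts
                      if not (q1 - 0.5 * (q3 - q1) <= x
                              <= q3 + 1.5 * (q3 - q1))}
    assert set(removed["rt_seconds"]) == expect_removed == {100}


def test_boundary_values_kept():
    rec = toy_records([1, 2, 3, 4, 5, 6, 7, 100])
    (b,) = compute_iqr_bounds(rec)
    probe = toy_records([b.lower, b.upper])
    kept, removed = filter_outliers(probe, [b])
    assert len(kept) == 2 and removed.empty


def test_empty_input_filter():
    rec = toy_records([1, 2, 3, 4])
    bounds = compute_iqr_bounds(rec)
    kept, removed = filter_outliers(rec.iloc[:0], bounds)
    assert kept.empty and removed.empty


def test_small_item_raises_with_item_name():
    rec = toy_records([1, 2, 3], item="appetite")
    with pytest.raises(ValueError, match="appetite"):
        compute_iqr_bounds(rec)


def test_filter_idempotent(default_cohort):
    _, records, _, _ = default_cohort
    bounds = compute_iqr_bounds(records)
    kept, _ = filter_outliers(records, bounds)
    kept2, removed2 = filter_outliers(kept, bounds)
    assert removed2.empty
    pd.testing.assert_frame_equal(kept, kept2)


def test_injected_outliers_recovered():
    """Removal fraction brackets the injected rate (binomial 99% band)."""
    cfg = SimConfig(outlier_rate=0.05, outlier_scale=8.0, seed=31)
    records, _, _ = generate_cohort(cfg)
    bounds = compute_iqr_bounds(records)
    _, removed = filter_outliers(records, bounds)
    n = len(records)
    frac = len(removed) / n
    half_width = 2.58 * np.sqrt(0.05 * 0.95 / n)
    # the IQR rule also clips some honest tail mass, so allow one-sided slack
    assert 0.05 - half_width <= frac <= 0.05 + half_width + 0.05


def test_two_point_cell_standardizes_to_unit():
    rec = toy_records([2, 4])
    zrt, audit = z_standardize(rec)
    assert sorted(zrt["z"]) == [-1.0, 1.0]
    assert audit["zero_sd_cells"] == 0


def test_constant_cell_dropped_and_audited():
    rec = toy_records([3, 3, 3])
    zrt, audit = z_standardize(rec)
    assert zrt.empty
    assert audit["zero_sd_cells"] == 1


def test_singleton_cell_dropped():
    rec = toy_records([3.0])
    zrt, audit = z_standardize(rec)
    assert zrt.empty and audit["small_cells"] == 1


def test_random_cell_recomputation():
    rng = np.random.default_rng(0)
    rts = rng.lognormal(1, 0.4, 50)
    rec = toy_records(rts)
    zrt, _ = z_standardize(rec)
    z = zrt.sort_values("day_index")["z"].to_numpy()
    expect = (rts - rts.mean()) / rts.std(ddof=0)
    np.testing.assert_allclose(z, expect, atol=1e-12)
    assert abs(z.mean()) < 1e-12
    assert abs(z.std(ddof=0) - 1) < 1e-12


def test_cell_normalization_invariant(default_cohort):
    """Every retained cell has mean 0 and unit SD to 1e-9."""
    _, records, _, _ = default_cohort
    result = preprocess(records)
    g = result["zrt"].groupby(["subject_id", "item", "option"])["z"]
    assert g.mean().abs().max() < 1e-9
    assert (g.apply(lambda x: x.std(ddof=0)) - 1).abs().max() < 1e-9


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.randoms(use_true_random=False))
def test_order_invariance(rand):
    cfg = SimConfig(n_subjects=6, n_days=8, seed=13)
    records, _, _ = generate_cohort(cfg)
    perm = records.sample(frac=1, random_state=rand.randrange(2 ** 31))
    b1 = {b.item: b for b in compute_iqr_bounds(records)}
    b2 = {b.item: b for b in compute_iqr_bounds(perm)}
    assert b1 == b2
    z1, _ = z_standardize(records)
    z2, _ = z_standardize(perm)
    pd.testing.assert_frame_equal(z1, z2)
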