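"""Raster I/O, focal-mean imputation, grading, and zonal aggregation."""

import numpy as np
import pytest

from stbhm import (
    GradeScheme,
    RasterGrid,
    WHO_GRADE_SCHEME,
    ZoneLabels,
    area_percent_by_grade,
    build_panel,
    classify_grades,
    impute_focal,
    read_raster,
    write_raster,
    zonal_mean,
)
from stbhm.geodata import RasterParseError, _window_offsets


def _grid(values, mask=None, year=None):
    return RasterGrid(values=np.asarray(values, dtype=float), missing_mask=mask, year=year)


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------


def test_read_raster_masks_nodata(tmp_path):
    p = tmp_path / "g.asc"
    p.write_text("ncols 2\nnrows 2\ncellsize 0.1\nNODATA_value -9999\n1 2\n-9999 4\n")
    g = read_raster(p)
    assert g.shape == (2, 2)
    assert g.n_missing == 1
    assert g.missing_mask[1, 0]
    assert g.values[0, 1] == 2.0


@pytest.mark.parametrize(
    "body, msg",
    [
        ("ncols 3\nnrows 1\n1 2 3 4\n", "columns"),
        ("ncols 2\nnrows 2\n1 2\n", "rows"),
        ("ncols 2\nnrows 1\n1 abc\n", "non-numeric"),
        ("nrows 1\n1\n", "ncols"),
    ],
)
def test_read_raster_parse_errors(tmp_path, body, msg):
    p = tmp_path / "bad.asc"
    p.write_text(body)
    with pytest.raises(RasterParseError, match=msg):
        read_raster(p)


def test_raster_roundtrip_identity(tmp_path, rng):
    values = rng.uniform(0, 80, size=(7, 5))
    mask = rng.random((7, 5)) < 0.2
    g = _grid(np.where(mask, 0.0, values), mask)
    p = tmp_path / "rt.asc"
    write_raster(g, p)
    g2 = read_raster(p)
    np.testing.assert_array_equal(g.missing_mask, g2.missing_mask)
    np.testing.assert_allclose(g.values[~mask], g2.values[~mask], rtol=1e-9)


# ---------------------------------------------------------------------------
# focal-mean imputation
# ---------------------------------------------------------------------------


def _impute_oracle(values, mask, window):
    """Brute-force Jacobi focal-mean imputation via explicit loops."""
    values = values.copy()
    mask = mask.copy()
    lo, hi = _window_offsets(window)
    while mask.any():
        new_vals = values.copy()
        new_mask = mask.copy()
        filled_any = False
        for r in range(values.shape[0]):
            for c in range(values.shape[1]):
                if not mask[r, c]:
                    continue
                obs = [
                    values[rr, cc]
                    for rr in range(max(0, r + lo), min(values.shape[0], r + hi + 1))
                    for cc in range(max(0, c + lo), min(values.shape[1], c + hi + 1))
                    if not mask[rr, cc]
                ]
                if obs:
                    new_vals[r, c] = np.mean(obs)
                    new_mask[r, c] = False
                    filled_any = True
        if not filled_any:
            raise RuntimeError("stuck")
        values, mask = new_vals, new_mask
    return values


def test_impute_noop_on_fully_observed(rng):
    g = _grid(rng.uniform(1, 2, (4, 4)))
    out = impute_focal(g)
    np.testing.assert_array_equal(out.values, g.values)


def test_impute_single_hole_constant_neighbourhood():
    vals = np.full((5, 5), 7.0)
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 2] = True
    out = impute_focal(_grid(vals, mask))
    assert out.n_missing == 0
    assert out.values[2, 2] == pytest.approx(7.0)


@pytest.mark.parametrize("window", [3, 4, 6])
def test_impute_matches_bruteforce_oracle(window, rng):
    rows, cols = np.meshgrid(np.arange(5.0), np.arange(5.0), indexing="ij")
    vals = 1.0 + rows + 2 * cols  # linear ramp
    mask = np.zeros((5, 5), dtype=bool)
    mask[1:3, 2:4] = True
    out = impute_focal(_grid(np.where(mask, 0, vals), mask), window=window)
    expected = _impute_oracle(vals, mask, window)
    np.testing.assert_allclose(out.values, expected, rtol=1e-12)


def test_impute_idempotent_and_bounded(rng):
    vals = rng.uniform(10, 50, (8, 8))
    mask = rng.random((8, 8)) < 0.4
    g = _grid(np.where(mask, 0, vals), mask)
    out = impute_focal(g)
    assert out.n_missing == 0
    again = impute_focal(out)
    np.testing.assert_array_equal(out.values, again.values)
    obs = vals[~mask]
    assert out.values.min() >= obs.min() - 1e-12
    assert out.values.max() <= obs.max() + 1e-12


def test_impute_all_missing_errors():
    mask = np.ones((3, 3), dtype=bool)
    with pytest.raises(ValueError, match="all-missing"):
        impute_focal(_grid(np.zeros((3, 3)), mask))


def test_impute_max_iter_reports_remaining():
    mask = np.ones((30, 30), dtype=bool)
    mask[0, 0] = False
    vals = np.zeros((30, 30))
    vals[0, 0] = 5.0
    with pytest.raises(ValueError, match="still missing"):
        impute_focal(_grid(vals, mask), window=3, max_iter=2)


# ---------------------------------------------------------------------------
# grades and area shares
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "value, grade",
    [(10.0, 1), (72.0, 5), (25.0, 3), (14.999, 1), (15.0, 2), (70.0, 5)],
)
def test_classify_grades_band_edges(value, grade):
    g = _grid([[value]])
    assert classify_grades(g, WHO_GRADE_SCHEME)[0, 0] == grade


def test_grade_scheme_rejects_unordered_breaks():
    with pytest.raises(ValueError, match="increasing"):
        GradeScheme(breaks=(25.0, 15.0))


def test_classify_grades_shift_invariance(rng):
    vals = rng.uniform(0, 100, (6, 6))
    breaks = np.asarray(WHO_GRADE_SCHEME.breaks)
    gap = np.min(np.abs(vals[:, :, None] - breaks[None, None, :]))
    delta = 0.5 * gap
    a = classify_grades(_grid(vals))
    b = classify_grades(_grid(vals + delta))
    np.testing.assert_array_equal(a, b)


def test_area_percent_uniform_and_split():
    uniform = area_percent_by_grade(np.full((4, 4), 3), grades=range(1, 6))
    assert uniform[3] == pytest.approx(100.0)
    assert uniform.drop(3).sum() == pytest.approx(0.0)
    half = np.ones((2, 4), dtype=int)
    half[1] = 5
    pct = area_percent_by_grade(half)
    assert pct[1] == pytest.approx(50.0)
    assert pct[5] == pytest.approx(50.0)


def test_area_percent_matches_counting_oracle(rng):
    grades = rng.integers(1, 6, size=(20, 20))
    zones = ZoneLabels(labels=(rng.random((20, 20)) < 0.8).astype(int))
    pct = area_percent_by_grade(grades, zones=zones, grades=range(1, 6))
    inside = grades[zones.labels > 0]
    for g in range(1, 6):
        count = sum(1 for v in inside.ravel() if v == g)
        assert pct[g] == pytest.approx(100.0 * count / inside.size, abs=1e-12)
    assert pct.sum() == pytest.approx(100.0, abs=1e-9)


def test_area_percent_empty_area_errors():
    with pytest.raises(ValueError, match="empty"):
        area_percent_by_grade(np.ones((2, 2), dtype=int), zones=ZoneLabels(np.zeros((2, 2), dtype=int)))


# ---------------------------------------------------------------------------
# zonal aggregation and panels
# ---------------------------------------------------------------------------


def test_zonal_mean_simple_cases():
    zones = ZoneLabels(labels=np.array([[1, 1], [1, 1]]))
    assert zonal_mean(_grid(np.full((2, 2), 4.2)), zones)[0] == pytest.approx(4.2)
    zones2 = ZoneLabels(labels=np.array([[1, 1], [2, 0]]))
    vals = np.array([[1.0, 3.0], [5.0, 99.0]])
    np.testing.assert_allclose(zonal_mean(_grid(vals), zones2), [2.0, 5.0])


def test_zonal_mean_matches_loop_oracle(rng):
    labels = rng.integers(1, 11, size=(30, 30))
    zones = ZoneLabels(labels=labels)
    vals = rng.uniform(0, 50, (30, 30))
    means = zonal_mean(_grid(vals), zones)
    for u in range(1, 11):
        assert means[u - 1] == pytest.approx(vals[labels == u].mean(), rel=1e-12)


def test_zonal_mean_constant_within_zone_exact(rng):
    labels = rng.integers(1, 5, size=(10, 10))
    consts = {1: 3.0, 2: 8.5, 3: 1.25, 4: 40.0}
    vals = np.vectorize(consts.get)(labels)
    means = zonal_mean(_grid(vals), ZoneLabels(labels=labels))
    np.testing.assert_array_equal(means, [consts[u] for u in range(1, 5)])


def test_build_panel_centers_time():
    zones = ZoneLabels(labels=np.ones((2, 2), dtype=int))
    grids = [_grid(np.full((2, 2), 30.0), year=y) for y in range(1998, 2015)]
    panel = build_panel(grids, zones)
    assert panel.tstar.min() == -8 and panel.tstar.max() == 8
    assert panel.tstar.mean() == pytest.approx(0.0)
    np.testing.assert_allclose(panel.values, 30.0)


def test_build_panel_matches_zonal_means(rng):
    labels = rng.integers(1, 6, size=(12, 12))
    zones = ZoneLabels(labels=labels)
    grids = [_grid(rng.uniform(5, 60, (12, 12)), year=2000 + k) for k in range(4)]
    panel = build_panel(grids, zones)
    for k, g in enumerate(grids):
        np.testing.assert_allclose(panel.values[:, k], zonal_mean(g, zones))


def test_build_panel_rejects_year_gaps():
    zones = ZoneLabels(labels=np.ones((2, 2), dtype=int))
    grids = [_grid(np.ones((2, 2)), year=y) for y in (2000, 2002)]
    with pytest.raises(ValueError, match="consecutive"):
        build_panel(grids, zones)
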