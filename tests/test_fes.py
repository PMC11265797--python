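"""WHAM, projection, alignment, convergence bands, basin/barrier readouts."""

import numpy as np
import pytest

from altaccess import units
from altaccess.errors import ValidationError
from altaccess.colvar import CVSeries
from altaccess.fes import (PMFGrid, align_pmf, basin_barrier_report,
                           convergence_band, pmf_from_csv, pmf_to_csv,
                           project_pmf, wham)
from altaccess.sampling import (BiasSpec, LangevinParams, UmbrellaWindow,
                                make_umbrella_campaign)
from altaccess.surfaces import Harmonic, analytic_pmf_1d


def _window_from_values(values, bias, **kw):
    values = np.asarray(values, dtype=float)
    series = CVSeries(
        tuple(f"cv{i+1}" for i in range(values.shape[1] if values.ndim == 2 else 1)),
        np.arange(len(values), dtype=float),
        values if values.ndim == 2 else values[:, None],
    )
    return UmbrellaWindow(series, bias, **kw)


# -------------------------------------------------------------------- wham

def test_single_unbiased_window_reduces_to_log_histogram():
    rng = np.random.default_rng(0)
    samples = rng.normal(0.0, 0.2, 50_000)
    win = _window_from_values(samples, BiasSpec((0.0,), (0.0,)))
    grid = wham([win], bins=32)
    counts, _ = np.histogram(samples, bins=grid.edges[0])
    expected = -units.kt() * np.log(counts[grid.defined] / counts.sum())
    expected -= expected.min()
    np.testing.assert_allclose(grid.values[grid.defined], expected, atol=1e-8)


def test_harmonic_surface_recovered_by_12_windows():
    """Umbrella windows on U = k x^2 / 2 recover the quadratic."""
    k = units.kj_to_kcal(400.0)
    surf = Harmonic((k,))
    centres = np.linspace(-0.6, 0.6, 12)[:, None]
    params = LangevinParams(timestep=1e-4, friction=1.0, n_steps=400_000,
                            stride=40, seed=13)
    windows = make_umbrella_campaign(surf, centres, [[units.kj_to_kcal(800.0)]], params)
    # grid restricted to the window-covered range; auto-ranged grids put
    # their outermost bins in barely-sampled territory
    grid = wham(windows, bins=[np.linspace(-0.63, 0.63, 41)])
    truth = analytic_pmf_1d(surf, grid.centres[0][grid.defined])
    diff = grid.values[grid.defined] - truth
    diff -= diff.mean()
    assert np.sqrt((diff**2).mean()) <= 0.1


def test_wham_invariant_to_window_order_and_tier_split(campaign_1d):
    _, windows = campaign_1d
    sub = windows[:8]
    edges = np.linspace(0.15, 0.55, 40)
    a = wham(sub, bins=[edges])
    b = wham(list(reversed(sub)), bins=[edges])
    np.testing.assert_allclose(
        a.values[a.defined], b.values[b.defined], atol=1e-6
    )
    # duplicating a window's samples across two tier labels is a no-op
    # relative to concatenating them into one window
    w = sub[0]
    half = w.samples.n_frames // 2
    first = _window_from_values(w.samples.values[:half], w.bias, tier="tier0")
    second = _window_from_values(w.samples.values[half:], w.bias, tier="tier1")
    split = wham([first, second, *sub[1:]], bins=[edges])
    np.testing.assert_allclose(
        split.values[split.defined], a.values[a.defined], atol=1e-6
    )


def test_disconnected_windows_warn():
    rng = np.random.default_rng(1)
    far_apart = [
        _window_from_values(rng.normal(0.0, 0.01, 2000), BiasSpec((0.0,), (1000.0,))),
        _window_from_values(rng.normal(5.0, 0.01, 2000), BiasSpec((5.0,), (1000.0,))),
    ]
    with pytest.warns(UserWarning, match="disconnected"):
        wham(far_apart, bins=[np.linspace(-0.2, 5.2, 200)])


# -------------------------------------------------------------- projection

def _grid_from_function(f, x_edges, y_edges, temperature=units.DEFAULT_TEMPERATURE):
    xc = 0.5 * (x_edges[1:] + x_edges[:-1])
    yc = 0.5 * (y_edges[1:] + y_edges[:-1])
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    vals = f(xx, yy)
    return PMFGrid((x_edges, y_edges), vals, np.ones_like(vals, bool), temperature)


def test_projection_of_separable_surface_recovers_x_part():
    x_edges = np.linspace(-1, 1, 41)
    y_edges = np.linspace(-1, 1, 31)
    grid = _grid_from_function(lambda x, y: 2.0 * x**2 + 3.0 * np.abs(y), x_edges, y_edges)
    proj = project_pmf(grid, axis=1)
    xc = proj.centres[0]
    expected = 2.0 * xc**2
    expected -= expected.min()
    np.testing.assert_allclose(proj.values, expected, atol=1e-10)


def test_projection_gaussian_integral_closed_form():
    """F2 = (x^2 + y^2)/2 at kT = 1 projects to x^2/2 + const."""
    temperature = 1.0 / units.KB_KCAL  # kT exactly 1 kcal/mol
    x_edges = np.linspace(-3, 3, 61)
    y_edges = np.linspace(-8, 8, 1601)  # wide, fine y-grid for the integral
    grid = _grid_from_function(lambda x, y: 0.5 * (x**2 + y**2), x_edges, y_edges,
                               temperature)
    proj = project_pmf(grid, axis=1)
    xc = proj.centres[0]
    expected = 0.5 * xc**2
    expected -= expected.min()
    np.testing.assert_allclose(proj.values, expected, atol=2e-3)


def test_single_defined_row_reproduced():
    x_edges = np.linspace(0, 1, 5)
    y_edges = np.linspace(0, 1, 4)
    vals = np.full((4, 3), np.inf)
    defined = np.zeros((4, 3), bool)
    vals[2] = [1.0, 0.3, 0.9]
    defined[2] = True
    grid = PMFGrid((x_edges, y_edges), vals, defined)
    proj = project_pmf(grid, axis=2)
    np.testing.assert_allclose(proj.values, np.array([1.0, 0.3, 0.9]) - 0.3, atol=1e-12)
    assert proj.defined.all()


def test_projection_commutes_with_additive_constant(campaign_2d):
    _, windows = campaign_2d
    grid = wham(windows[:48], bins=(48, 32))
    shifted = grid.shifted(3.7)
    a = project_pmf(grid, axis=1)
    b = project_pmf(shifted, axis=1)
    np.testing.assert_allclose(a.values[a.defined], b.values[b.defined], atol=1e-9)


# --------------------------------------------------------------- alignment

def _profile(values, lo=0.0, hi=1.0, defined=None):
    values = np.asarray(values, dtype=float)
    edges = np.linspace(lo, hi, values.size + 1)
    if defined is None:
        defined = np.isfinite(values)
    return PMFGrid((edges,), np.where(defined, values, np.inf), defined)


def test_align_to_self_is_identity():
    p = _profile([0.0, 1.0, 0.5, 2.0])
    aligned = align_pmf(p, reference=p)
    np.testing.assert_allclose(aligned.values, p.values)


def test_align_removes_constant_offset():
    p = _profile([0.0, 1.0, 0.5, 2.0])
    shifted = p.shifted(5.0)
    aligned = align_pmf(shifted, reference=p)
    np.testing.assert_allclose(aligned.values, p.values, atol=1e-12)


def test_partial_overlap_alignment_is_mean_difference():
    ref = _profile([0.0, 1.0, 0.5, np.inf], defined=np.array([1, 1, 1, 0], bool))
    cur = _profile([np.inf, 3.0, 1.5, 2.0], defined=np.array([0, 1, 1, 1], bool))
    aligned = align_pmf(cur, reference=ref)
    shift = ((1.0 - 3.0) + (0.5 - 1.5)) / 2.0
    np.testing.assert_allclose(aligned.values[1:], np.array([3.0, 1.5, 2.0]) + shift)


def test_region_alignment_zeroes_region_mean():
    p = _profile([4.0, 2.0, 1.0, 3.0], lo=0.0, hi=4.0)
    aligned = align_pmf(p, region=(0.0, 2.0))  # bins centred at 0.5, 1.5
    assert aligned.values[:2].mean() == pytest.approx(0.0, abs=1e-12)


def test_alignment_without_overlap_fails():
    ref = _profile([0.0, np.inf], defined=np.array([1, 0], bool))
    cur = _profile([np.inf, 1.0], defined=np.array([0, 1], bool))
    with pytest.raises(ValidationError):
        align_pmf(cur, reference=ref)


# -------------------------------------------------------- convergence band

def test_identical_halves_give_zero_band():
    """A window whose first and last halves are identical yields a band
    equal to the alignment residual, i.e. ~0."""
    rng = np.random.default_rng(2)
    half = rng.normal(0.5, 0.1, 5000)
    values = np.concatenate([half, half])
    win = _window_from_values(values, BiasSpec((0.5,), (0.0,)))
    band = convergence_band([win], fractions=((0.0, 0.5), (0.5, 1.0), (0.0, 1.0)),
                            bins=24)
    widths = band.widths[np.isfinite(band.widths)]
    assert np.nanmax(widths) < 0.02  # half-vs-full binning noise only


def test_full_curve_inside_band(campaign_1d):
    _, windows = campaign_1d
    band = convergence_band(windows[:24], bins=48)
    full = band.curves["0.00-1.00"]
    ok = np.isfinite(full)
    assert np.all(full[ok] <= band.upper[ok] + 1e-12)
    assert np.all(full[ok] >= band.lower[ok] - 1e-12)


# ------------------------------------------------------------ basin report

def test_constructed_double_well_report():
    """Minima at (-1, 0) and (+1, 3) with saddle 6: dG = 3, barrier 6."""
    x = np.linspace(-2, 2, 401)
    left = 0.0 + 6.0 * (1 - np.cos(np.pi * (x + 1))) / 2
    right = 3.0 + 3.0 * (1 - np.cos(np.pi * (x - 1))) / 2
    values = np.where(x < 0, left, right)
    p = _profile(values, lo=-2, hi=2)
    rep = basin_barrier_report(p)
    minima = rep["minima"]
    assert len(minima) == 2
    np.testing.assert_allclose(minima["position"], [-1.0, 1.0], atol=0.02)
    np.testing.assert_allclose(minima["delta_g"], [0.0, 3.0], atol=0.01)
    barriers = rep["barriers"]
    assert barriers["saddle_value"].iloc[0] == pytest.approx(6.0, abs=0.01)
    assert barriers["barrier_from_left"].iloc[0] == pytest.approx(6.0, abs=0.01)
    assert barriers["barrier_from_right"].iloc[0] == pytest.approx(3.0, abs=0.01)
    assert barriers["delta_g_right_minus_left"].iloc[0] == pytest.approx(3.0, abs=0.01)


def test_single_well_and_monotone_profiles():
    x = np.linspace(-1, 1, 101)
    rep = basin_barrier_report(_profile(x**2, lo=-1, hi=1))
    assert len(rep["minima"]) == 1
    assert rep["barriers"].empty
    rep2 = basin_barrier_report(_profile(x, lo=-1, hi=1))
    assert rep2["minima"].empty
    assert rep2["note"]


def test_symmetric_double_well_equal_basins():
    x = np.linspace(-1.5, 1.5, 301)
    values = 3.0 * ((x**2 - 1.0) ** 2)
    rep = basin_barrier_report(_profile(values, lo=-1.5, hi=1.5))
    np.testing.assert_allclose(rep["minima"]["delta_g"], [0.0, 0.0], atol=1e-9)


def test_prominence_pruning_drops_jitter_minima():
    x = np.linspace(-1.5, 1.5, 301)
    values = 3.0 * ((x**2 - 1.0) ** 2) + 0.05 * np.sin(40 * x)
    pruned = basin_barrier_report(_profile(values, lo=-1.5, hi=1.5), min_prominence=0.5)
    assert len(pruned["minima"]) == 2


# ---------------------------------------------------------------- csv i/o

def test_pmf_csv_roundtrip_1d(tmp_path):
    p = _profile([0.0, 1.0, np.inf, 2.0], defined=np.array([1, 1, 0, 1], bool))
    path = tmp_path / "pmf.csv"
    pmf_to_csv(p, path)
    back = pmf_from_csv(path)
    np.testing.assert_allclose(back.values[back.defined], p.values[p.defined])
    np.testing.assert_array_equal(back.defined, p.defined)


def test_pmf_csv_roundtrip_2d(tmp_path):
    x_edges = np.linspace(0, 1, 5)
    y_edges = np.linspace(0, 2, 4)
    vals = np.arange(12, dtype=float).reshape(4, 3)
    grid = PMFGrid((x_edges, y_edges), vals, np.ones((4, 3), bool))
    path = tmp_path / "pmf2.csv"
    pmf_to_csv(grid, path)
    back = pmf_from_csv(path)
    np.testing.assert_allclose(back.values, grid.values)
    np.testing.assert_allclose(back.edges[0], x_edges, atol=1e-12)
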