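"""Lineage statistics: cycle times, rates, decomposition, correlations,
arrest labelling and probabilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from histogrowth import stats as hs
from histogrowth.lineage import (FATE_CENSORED, FATE_DIVIDED, FATE_EXTRUDED,
                                 LineageForest)
from histogrowth.stats import (ArrestSchedule, InsufficientDataError,
                               RateSeries, hill)

from conftest import make_cell


# ---------------------------------------------------------------------------
# cycle times

def test_cycle_times_basic(tiny_forest):
    entries = hs.cycle_times(tiny_forest)
    assert len(entries) == 1
    assert entries[0].cycle_time == pytest.approx(2.7)


def test_cycle_times_empty_for_divisionless_forest():
    f = LineageForest(records=[make_cell("a", None, 0, 5, FATE_CENSORED)],
                      movie_end=5)
    assert hs.cycle_times(f) == []


def test_cycle_times_exclude_sop_and_extruded():
    f = LineageForest(records=[
        make_cell("a", None, 0, 4, FATE_DIVIDED),
        make_cell("b", "a", 4, 8, FATE_DIVIDED, is_sop=True),
        make_cell("b1", "b", 8, 12, FATE_CENSORED),
        make_cell("b2", "b", 8, 12, FATE_CENSORED),
        make_cell("c", "a", 4, 9, FATE_EXTRUDED),
    ], movie_end=12)
    assert [e.cell_id for e in hs.cycle_times(f)] == ["a"]


@pytest.mark.parametrize("vals, expected", [
    ([4.0, 4.0, 4.0], (4.0, 0.0, 0.0)),
    # sample (n-1) sd: {3, 5} -> sd = sqrt(2)
    ([3.0, 5.0], (4.0, math.sqrt(2.0), math.sqrt(2.0) / 4.0)),
])
def test_cycle_time_summary(vals, expected):
    assert hs.cycle_time_summary(vals) == pytest.approx(expected)


def test_cycle_time_summary_needs_two():
    with pytest.raises(InsufficientDataError):
        hs.cycle_time_summary([4.0])


# ---------------------------------------------------------------------------
# division rate / spectrum / peaks

def test_division_rate_zero_without_divisions():
    f = LineageForest(records=[make_cell("a", None, 0, 10, FATE_CENSORED)],
                      movie_end=10)
    rs = hs.division_rate(f, grid_step=0.5)
    assert np.nanmax(rs.rate) == 0.0


def test_division_rate_hand_computed_window_average():
    # one division at t=5: 2 cells alive before, 3 after; evaluated at
    # t=5 with w=0.875 the window-averaged count is 2.5 and the rate
    # 1/(0.875*2.5)
    f = LineageForest(records=[
        make_cell("m", None, 0.0, 5.0, FATE_DIVIDED),
        make_cell("d1", "m", 5.0, 20.0, FATE_CENSORED),
        make_cell("d2", "m", 5.0, 20.0, FATE_CENSORED),
        make_cell("o", None, 0.0, 20.0, FATE_CENSORED),
    ], movie_end=20.0)
    rs = hs.division_rate(f, window=0.875, grid_step=0.5, t_start=5.0,
                          t_end=5.0)
    assert rs.rate[0] == pytest.approx(1.0 / (0.875 * 2.5))
    rs_inst = hs.division_rate(f, window=0.875, grid_step=0.5, t_start=5.0,
                               t_end=5.0, denominator="instantaneous")
    assert rs_inst.rate[0] == pytest.approx(1.0 / (0.875 * 3.0))


def test_division_rate_permutation_invariant(base_forest):
    rs1 = hs.division_rate(base_forest, t_start=16, t_end=28, grid_step=0.25)
    shuffled = LineageForest(records=list(reversed(base_forest.records)),
                             movie_end=base_forest.movie_end)
    rs2 = hs.division_rate(shuffled, t_start=16, t_end=28, grid_step=0.25)
    np.testing.assert_allclose(rs1.rate, rs2.rate)


def test_rate_integral_counts_divisions():
    # integral of unsmoothed per-capita rate x alive count recovers the
    # division count (smoothing conservation at window << grid extent)
    from histogrowth.sim import default_config, simulate
    f = simulate(default_config(seed=9, t_end=24.0)).forest
    step = 0.05
    rs = hs.division_rate(f, window=step, grid_step=step,
                          t_start=0.0, t_end=24.0)
    births = np.sort([r.birth_time for r in f.records])
    ends = np.sort([r.end_time for r in f.records])
    nbar = np.array([
        (np.minimum(ends, t + step / 2) - np.maximum(births, t - step / 2))
        .clip(min=0).sum() / step for t in rs.times])
    total = np.nansum(rs.rate * nbar) * step
    n_div = sum(r.end_fate == FATE_DIVIDED for r in f.records)
    assert total == pytest.approx(n_div, rel=0.01)


def test_spectrum_constant_rate_is_flat():
    t = np.arange(0, 12, 0.25)
    rs = RateSeries(times=t, rate=np.full_like(t, 0.3), window=0.875)
    _f, mag = hs.division_rate_spectrum(rs, t_max=12)
    assert mag[0] == 1.0
    assert np.all(mag[1:] < 1e-12)


def test_spectrum_sinusoid_peaks_at_its_frequency():
    t = np.arange(0, 12, 0.125)
    rs = RateSeries(times=t, rate=0.5 + 0.1 * np.cos(2 * np.pi * t / 4.0),
                    window=0.875)
    freqs, mag = hs.division_rate_spectrum(rs, t_max=12)
    assert freqs[1 + np.argmax(mag[1:])] == pytest.approx(0.25, abs=1e-9)


def test_spectrum_rejects_nonuniform_grid():
    rs = RateSeries(times=np.array([0.0, 1.0, 3.0]),
                    rate=np.array([1.0, 1.0, 1.0]), window=0.875)
    with pytest.raises(ValueError, match="resample"):
        hs.division_rate_spectrum(rs)


def test_count_peaks_monotone_and_sinusoid():
    t = np.arange(0, 12.01, 0.125)
    mono = RateSeries(times=t, rate=t / 12.0, window=0.875)
    assert hs.count_peaks(mono, 0, 12, 0.1) == 0
    sine = RateSeries(times=t, rate=0.5 + 0.2 * np.sin(2 * np.pi * t / 4.0),
                      window=0.875)
    assert hs.count_peaks(sine, 0, 12.01, 0.1) == 3


# ---------------------------------------------------------------------------
# growth decomposition

def _forest_with_areas(records, movie_end):
    return LineageForest(records=records, movie_end=movie_end)


def test_decomposition_pure_area_growth():
    # constant cell count, all areas doubled -> everything in area change
    cells = [make_cell(f"c{i}", None, 0.0, 2.0, FATE_CENSORED,
                       area_series=[(0.0, 10.0), (1.0, 15.0), (2.0, 20.0)])
             for i in range(4)]
    d = hs.growth_decomposition(_forest_with_areas(cells, 2.0))
    assert d.cum_total[-1] == pytest.approx(math.log(2.0))
    assert d.cum_area_change[-1] == pytest.approx(math.log(2.0))
    assert d.cum_division[-1] == 0.0
    assert d.cum_extrusion[-1] == 0.0


def test_decomposition_single_division():
    # N: 2 -> 3 via one division.  With the mother's area split between
    # her daughters, total area is conserved: division contributes
    # ln(3/2), mean-cell-area change -ln(3/2), total 0.
    cells = [
        make_cell("m", None, 0.0, 1.0, FATE_DIVIDED,
                  area_series=[(0.0, 10.0), (1.0, 10.0)]),
        make_cell("d1", "m", 1.0, 2.0, FATE_CENSORED,
                  area_series=[(1.0, 5.0), (2.0, 5.0)]),
        make_cell("d2", "m", 1.0, 2.0, FATE_CENSORED,
                  area_series=[(1.0, 5.0), (2.0, 5.0)]),
        make_cell("o", None, 0.0, 2.0, FATE_CENSORED,
                  area_series=[(0.0, 10.0), (1.0, 10.0), (2.0, 10.0)]),
    ]
    d = hs.growth_decomposition(_forest_with_areas(cells, 2.0))
    assert d.cum_division[-1] == pytest.approx(math.log(1.5))
    assert d.cum_area_change[-1] == pytest.approx(-math.log(1.5))
    assert d.cum_total[-1] == pytest.approx(0.0, abs=1e-12)

    # if instead every cell keeps area 10, mean cell area is unchanged
    # and the total grows by the division factor itself
    for c in cells:
        c.area_series = [(t, 10.0) for (t, _a) in c.area_series]
    d2 = hs.growth_decomposition(_forest_with_areas(cells, 2.0))
    assert d2.cum_area_change[-1] == pytest.approx(0.0, abs=1e-12)
    assert d2.cum_total[-1] == pytest.approx(math.log(1.5))


def test_decomposition_extrusion_is_negative():
    cells = [
        make_cell("a", None, 0.0, 1.5, FATE_EXTRUDED,
                  area_series=[(0.0, 10.0), (1.0, 10.0)]),
        make_cell("b", None, 0.0, 2.0, FATE_CENSORED,
                  area_series=[(0.0, 10.0), (1.0, 10.0), (2.0, 10.0)]),
        make_cell("c", None, 0.0, 2.0, FATE_CENSORED,
                  area_series=[(0.0, 10.0), (1.0, 10.0), (2.0, 10.0)]),
    ]
    d = hs.growth_decomposition(_forest_with_areas(cells, 2.0))
    assert d.cum_extrusion[-1] == pytest.approx(math.log(2.0 / 3.0))
    assert d.cum_division[-1] == 0.0


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_decomposition_closure_property(seed):
    """cum_total == cum_division + cum_area_change + cum_extrusion to
    1e-9 on randomized exact-area forests."""
    from histogrowth.sim import default_config
    from histogrowth.synth import gen_forest
    rng = np.random.default_rng(seed)
    cfg = default_config(seed=int(rng.integers(2 ** 31)),
                         t_end=float(rng.uniform(16.5, 20.0)),
                         n_init=int(rng.integers(2, 6)))
    res = gen_forest(cfg, geometry=True, frame_step=1.0)
    d = hs.growth_decomposition(res.forest)
    gap = d.cum_total - (d.cum_division + d.cum_area_change + d.cum_extrusion)
    assert np.max(np.abs(gap)) < 1e-9


# ---------------------------------------------------------------------------
# correlations

def test_identical_sisters_have_unit_correlation():
    recs = []
    for i, ct in enumerate([3.0, 4.0, 5.0, 6.0]):
        m = f"m{i}"
        recs.append(make_cell(m, None, 0.0, 1.0, FATE_DIVIDED))
        for s in ("a", "b"):
            cid = f"{m}{s}"
            recs.append(make_cell(cid, m, 1.0, 1.0 + ct, FATE_DIVIDED))
            for gs in ("x", "y"):
                recs.append(make_cell(cid + gs, cid, 1.0 + ct, 40.0,
                                      FATE_CENSORED))
    f = LineageForest(records=recs, movie_end=40.0)
    res = hs.pair_correlations(f, "sister", seed=0)
    assert res.pearson == pytest.approx(1.0)
    assert res.n_pairs == 4


def test_pair_correlations_rejects_zero_variance(tiny_forest):
    with pytest.raises((InsufficientDataError, ValueError)):
        hs.pair_correlations(tiny_forest, "sister")


# ---------------------------------------------------------------------------
# arrest labelling and probabilities

def test_label_arrested_definition():
    f = LineageForest(records=[
        make_cell("never", None, 20.0, 33.0, FATE_CENSORED),
        make_cell("div", None, 20.0, 25.0, FATE_DIVIDED),
        make_cell("d1", "div", 25.0, 33.0, FATE_CENSORED, is_sop=True),
        make_cell("d2", "div", 25.0, 30.0, FATE_EXTRUDED),
    ], movie_end=33.0)
    hs.label_arrested(f)
    assert f["never"].arrested is True
    assert f["div"].arrested is False
    assert f["d1"].arrested is False     # SOP: its own class
    assert f["d2"].arrested is False     # extruded


def test_label_arrested_min_followup_excludes_late_births():
    f = LineageForest(records=[
        make_cell("late", None, 32.0, 33.0, FATE_CENSORED),
        make_cell("early", None, 20.0, 33.0, FATE_CENSORED),
    ], movie_end=33.0)
    hs.label_arrested(f, min_followup=4.0)
    assert f["late"].arrested is None
    assert f["early"].arrested is True


def test_arrest_probabilities_all_double_arrest():
    recs = []
    for i in range(30):
        m = f"m{i}"
        t = 20.0 + (i % 10)
        recs.append(make_cell(m, None, t - 4, t, FATE_DIVIDED))
        recs.append(make_cell(m + "a", m, t, 33.0, FATE_CENSORED))
        recs.append(make_cell(m + "b", m, t, 33.0, FATE_CENSORED))
    f = hs.label_arrested(LineageForest(records=recs, movie_end=33.0))
    table, _sched = hs.arrest_probabilities(f, fit=False)
    assert np.all(table["p_hat"] == 1.0)
    assert np.all(table["alpha_hat"] == 1.0)


def test_arrest_hill_recovery_from_known_schedule():
    """t_half of the generating Hill curve recovered within 0.5 h from a
    forest with > 500 divisions."""
    from histogrowth.sim import default_config, simulate
    sched = ArrestSchedule(p_half_time=26.0, p_exponent=12.0, p_plateau=1.0,
                           alpha_half_time=26.0, alpha_exponent=12.0,
                           alpha_plateau=1.0)
    # run a little past the transition so the operational arrest label
    # (censored at movie end) has settled for divisions near t_half
    f = simulate(default_config(seed=11, arrest=sched, sop_prob=0.0,
                                t_end=36.0)).forest
    hs.label_arrested(f)
    table, fit = hs.arrest_probabilities(f, bin_width=1.0)
    assert table["n_div"].sum() > 500
    assert fit is not None
    assert abs(fit.p_half_time - 26.0) < 0.5


def test_fraction_arrested_created(base_forest):
    f = hs.label_arrested(base_forest)
    tab = hs.fraction_arrested_created(f, bin_width=1.0)
    early = tab[tab["t_mid"] < 20.0]["fraction"]
    late = tab[tab["t_mid"] > 29.0]["fraction"]
    assert float(early.max()) < 0.05
    assert float(late.min()) > 0.9


# ---------------------------------------------------------------------------
# binned relations / neighbors

def test_binned_relation_constant_and_linear():
    x = np.linspace(0, 1, 40)
    tab = hs.binned_relation(x, np.full_like(x, 7.0), n_bins=4)
    assert np.allclose(tab["y_mean"], 7.0)
    assert np.allclose(tab["y_sem"], 0.0)
    tab2 = hs.binned_relation(x, 2 * x, n_bins=4)
    assert np.allclose(tab2["y_mean"], 2 * tab2["x_mean"])


def test_binned_relation_flat_when_independent():
    rng = np.random.default_rng(4)
    area = rng.uniform(5, 25, size=2000)
    ct = rng.normal(4.5, 1.0, size=2000)      # no area dependence
    tab = hs.binned_relation(area, ct, n_bins=8)
    from scipy import stats as sstats
    fit = sstats.linregress(tab["x_mean"], tab["y_mean"])
    tstat = fit.slope / fit.stderr
    assert abs(tstat) < 2.0


def test_neighbor_correlation_null_and_positive_control():
    rng = np.random.default_rng(0)
    recs = []
    # four well-separated clusters, cycle times constant per cluster:
    # nearest neighbors always share a cluster, so rho is near 1
    for b, (bx, by, base_ct) in enumerate([(0, 0, 3.0), (100, 0, 5.0),
                                           (0, 100, 7.0), (100, 100, 9.0)]):
        for i in range(6):
            for j in range(6):
                cid = f"g{b}{i}{j}"
                ct = base_ct + rng.normal(0, 0.05)
                recs.append(make_cell(
                    cid, None, 0.0, ct + 1.0, FATE_DIVIDED,
                    centroid_series=[(0.0, bx + float(i), by + float(j))]))
                for s in ("a", "b"):
                    recs.append(make_cell(cid + s, cid, ct + 1.0, 40.0,
                                          FATE_CENSORED))
    f = LineageForest(records=recs, movie_end=40.0)
    res = hs.neighbor_cycle_correlation(f)
    assert res.pearson > 0.95

    # independent cycle times: |rho| small
    recs2 = []
    for i in range(12):
        for j in range(12):
            cid = f"h{i:02d}{j:02d}"
            ct = float(rng.normal(4.5, 1.0))
            ct = max(ct, 0.5)
            recs2.append(make_cell(cid, None, 0.0, ct + 1.0, FATE_DIVIDED,
                                   centroid_series=[(0.0, float(i), float(j))]))
            for s in ("a", "b"):
                recs2.append(make_cell(cid + s, cid, ct + 1.0, 40.0,
                                       FATE_CENSORED))
    f2 = LineageForest(records=recs2, movie_end=40.0)
    res2 = hs.neighbor_cycle_correlation(f2)
    assert abs(res2.pearson) <= 3.0 / math.sqrt(res2.n_pairs)
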