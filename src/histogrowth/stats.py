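"""Lineage-derived statistics: cycle times, division-rate series and
spectra, growth decomposition, cycle-time correlations, and the
arrest-probability (Hill) analysis.

All functions consume a :class:`~histogrowth.lineage.LineageForest`,
whether read from tracked movies or produced by the growth simulator,
and are invariant under permutation of the record order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, signal, stats as sstats

from .lineage import (FATE_CENSORED, FATE_DIVIDED, FATE_EXTRUDED,
                      CellTrackRecord, LineageForest)

__all__ = [
    "CycleTimeEntry", "RateSeries", "GrowthDecomposition", "ArrestSchedule",
    "CorrelationResult", "InsufficientDataError",
    "cycle_times", "cycle_time_summary", "division_rate",
    "division_rate_spectrum", "count_peaks", "growth_decomposition",
    "cycle_time_pairs", "pair_correlations", "label_arrested",
    "arrest_probabilities",
    "fraction_arrested_created", "binned_relation",
    "neighbor_cycle_correlation", "hill",
]

DEFAULT_WINDOW = 0.875  # h, top-hat smoothing window for the division rate


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class CycleTimeEntry:
    cell_id: str
    birth_time: float
    cycle_time: float


@dataclass
class RateSeries:
    """Per-capita event rate on a uniform time grid (events / h / cell)."""

    times: np.ndarray
    rate: np.ndarray          # NaN where the alive count vanished
    window: float

    def restrict(self, t_start: float, t_end: float) -> "RateSeries":
        m = (self.times >= t_start) & (self.times < t_end)
        return RateSeries(self.times[m], self.rate[m], self.window)


@dataclass
class GrowthDecomposition:
    """Cumulative log tissue-area expansion split into the isotropic
    contributions of division, cell-area change and extrusion."""

    times: np.ndarray
    cum_total: np.ndarray
    cum_division: np.ndarray
    cum_area_change: np.ndarray
    cum_extrusion: np.ndarray


@dataclass
class ArrestSchedule:
    """Hill-curve parameterization of the arrest probabilities.

    ``p(t)`` is the probability that a division at time t creates at
    least one arrested daughter; ``alpha(t)`` the probability that both
    daughters are arrested given at least one is.  Both are Hill curves
    ``plateau * t^n / (t_half^n + t^n)``, monotone increasing in t.
    """

    p_half_time: float
    p_exponent: float
    p_plateau: float
    alpha_half_time: float
    alpha_exponent: float
    alpha_plateau: float

    def __post_init__(self) -> None:
        for name in ("p_plateau", "alpha_plateau"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("p_exponent", "alpha_exponent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def p(self, t):
        return hill(t, self.p_half_time, self.p_exponent, self.p_plateau)

    def alpha(self, t):
        return hill(t, self.alpha_half_time, self.alpha_exponent,
                    self.alpha_plateau)


@dataclass
class CorrelationResult:
    pairing: str
    pearson: float
    spearman: float
    n_pairs: int


def hill(t, t_half: float, exponent: float, plateau: float = 1.0):
    """Monotone Hill curve ``plateau * t^n / (t_half^n + t^n)`` (t >= 0)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(t > 0, (t_half / np.maximum(t, 1e-300)) ** exponent,
                         np.inf)
    return plateau / (1.0 + ratio)


# ---------------------------------------------------------------------------
# cycle times

def cycle_times(forest: LineageForest) -> list[CycleTimeEntry]:
    """One entry per divided, non-SOP cell; censored and extruded cells
    carry no complete cycle and are excluded."""
    return [
        CycleTimeEntry(r.cell_id, r.birth_time, r.cycle_time)
        for r in forest.records
        if r.end_fate == FATE_DIVIDED and not r.is_sop
    ]


def cycle_time_summary(entries: Sequence[CycleTimeEntry] | Sequence[float]
                       ) -> tuple[float, float, float]:
    """(mean, sd, cv) of cycle times, with the sample (n-1) sd."""
    vals = np.array([e.cycle_time if isinstance(e, CycleTimeEntry) else e
                     for e in entries], dtype=float)
    if vals.size < 2:
        raise InsufficientDataError(
            f"need >= 2 cycle times, got {vals.size}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return mean, sd, sd / mean


# ---------------------------------------------------------------------------
# division rate

def division_rate(forest: LineageForest, window: float = DEFAULT_WINDOW,
                  grid_step: float = 0.125,
                  t_start: Optional[float] = None,
                  t_end: Optional[float] = None,
                  denominator: str = "window_mean") -> RateSeries:
    """Per-capita division rate on a uniform grid.

    At each grid time t the rate is ``(# divisions in [t-w/2, t+w/2)) /
    (w * Nbar(t))`` where ``Nbar`` is, by default, the time-average of
    the alive-cell count over the same window (``denominator="window_mean"``)
    or the instantaneous count (``denominator="instantaneous"``).  Grid
    points where the denominator vanishes are reported as NaN.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    div_times = np.sort([r.end_time for r in forest.records
                         if r.end_fate == FATE_DIVIDED])
    births = np.sort([r.birth_time for r in forest.records])
    ends = np.sort([r.end_time for r in forest.records])
    if t_start is None:
        t_start = float(births[0]) if births.size else 0.0
    if t_end is None:
        t_end = forest.movie_end
    times = np.arange(t_start, t_end + 1e-9, grid_step)

    def alive(t):
        return (np.searchsorted(births, t, side="right")
                - np.searchsorted(ends, t, side="right"))

    rate = np.empty_like(times)
    half = window / 2.0
    for i, t in enumerate(times):
        lo, hi = t - half, t + half
        n_div = (np.searchsorted(div_times, hi, side="left")
                 - np.searchsorted(div_times, lo, side="left"))
        if denominator == "instantaneous":
            nbar = float(alive(t))
        else:
            # exact time average of the piecewise-constant alive count:
            # integrate sum_i [birth_i <= s < end_i] over [lo, hi)
            overlap = (np.minimum(ends, hi) - np.maximum(births, lo)).clip(min=0.0)
            nbar = float(overlap.sum()) / window
        rate[i] = np.nan if nbar <= 0 else n_div / (window * nbar)
    return RateSeries(times=times, rate=rate, window=window)


def division_rate_spectrum(series: RateSeries, t_max: float = 28.5
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude of the Fourier transform of the rate before ``t_max``,
    normalized to its zero-frequency value."""
    t = series.times
    dt = np.diff(t)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("rate series must be on a uniform grid; resample")
    m = (t < t_max) & np.isfinite(series.rate)
    y = series.rate[m]
    if y.size < 2:
        raise InsufficientDataError("too few samples before t_max")
    spec = np.abs(np.fft.rfft(y))
    freqs = np.fft.rfftfreq(y.size, d=float(dt[0]))
    if spec[0] == 0:
        raise ValueError("zero mean rate: normalization undefined")
    return freqs, spec / spec[0]


def count_peaks(series: RateSeries, t_start: float, t_end: float,
                min_prominence: float = 0.1) -> int:
    """Local maxima located in [t_start, t_end) with prominence at
    least ``min_prominence`` times the window's global maximum.

    Peaks are detected on the whole series so that a maximum near the
    window edge keeps its true prominence (the surrounding data decide
    how prominent it is), then filtered to the window.
    """
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    y = np.nan_to_num(series.rate, nan=0.0)
    in_win = (series.times >= t_start) & (series.times < t_end)
    if not in_win.any() or y[in_win].max() <= 0:
        return 0
    thresh = min_prominence * float(y[in_win].max())
    peaks, _ = signal.find_peaks(y, prominence=thresh)
    return int(np.count_nonzero(in_win[peaks]))


# ---------------------------------------------------------------------------
# growth decomposition

def growth_decomposition(forest: LineageForest) -> GrowthDecomposition:
    """Split the cumulative log tissue-area expansion, frame interval by
    frame interval, into division, cell-area-change and extrusion parts.

    Writing the total apical area as ``A = N * abar`` (cell count times
    mean cell area), over one interval

        dln A = dln N + dln abar

    and the count change factors exactly into a division part
    ``ln((N0 + d) / N0)`` and an extrusion part ``ln(N1 / (N0 + d))``
    (d divisions net +d cells, extrusions net -1 each).  The closure
    ``cum_total = cum_division + cum_area_change + cum_extrusion`` is an
    identity of the construction, holding to float roundoff on exact
    input areas.
    """
    frames = sorted({t for r in forest.records if r.area_series
                     for (t, _a) in r.area_series})
    if len(frames) < 2:
        raise InsufficientDataError("need area series on >= 2 frames")
    # A censored cell counts as present on its final frame; a divided or
    # extruded cell does not (its daughters, if any, are).
    def present(r: CellTrackRecord, t: float) -> bool:
        if r.alive_at(t):
            return True
        return r.end_fate == FATE_CENSORED and math.isclose(t, r.end_time)

    area_at: list[dict[str, float]] = []
    for t in frames:
        frame_areas: dict[str, float] = {}
        for r in forest.records:
            if r.area_series and present(r, t):
                for (ts, a) in r.area_series:
                    if math.isclose(ts, t, abs_tol=1e-9):
                        frame_areas[r.cell_id] = a
                        break
        area_at.append(frame_areas)
    for t, fr in zip(frames, area_at):
        for r in forest.records:
            if present(r, t) and r.cell_id not in fr:
                raise ValueError(
                    f"cell {r.cell_id!r} alive at frame t={t} has no area")

    n = len(frames)
    d_tot = np.zeros(n - 1)
    d_div = np.zeros(n - 1)
    d_area = np.zeros(n - 1)
    d_ext = np.zeros(n - 1)
    for i in range(n - 1):
        t0, t1 = frames[i], frames[i + 1]
        a0, a1 = area_at[i], area_at[i + 1]
        n0, n1 = len(a0), len(a1)
        divisions = sum(1 for r in forest.records
                        if r.end_fate == FATE_DIVIDED and t0 < r.end_time <= t1)
        total0 = sum(a0.values())
        total1 = sum(a1.values())
        d_tot[i] = math.log(total1 / total0)
        d_div[i] = math.log((n0 + divisions) / n0)
        d_ext[i] = math.log(n1 / (n0 + divisions))
        d_area[i] = math.log((total1 / n1) / (total0 / n0))
    zeros = np.zeros(1)
    return GrowthDecomposition(
        times=np.asarray(frames, dtype=float),
        cum_total=np.concatenate([zeros, np.cumsum(d_tot)]),
        cum_division=np.concatenate([zeros, np.cumsum(d_div)]),
        cum_area_change=np.concatenate([zeros, np.cumsum(d_area)]),
        cum_extrusion=np.concatenate([zeros, np.cumsum(d_ext)]),
    )


# ---------------------------------------------------------------------------
# correlations

def cycle_time_pairs(forest: LineageForest, pairing: str,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Extract cycle-time pairs from one forest.

    ``pairing="mother_daughter"`` emits one pair per (mother, daughter)
    combination with both cells divided (up to two per mother);
    ``pairing="sister"`` emits one pair per sibling couple of divided
    cells, with the within-pair order randomized (seeded) since Pearson
    on unordered pairs depends on the ordering convention.
    """
    kids = forest.children_map()
    xs: list[float] = []
    ys: list[float] = []
    rng = np.random.default_rng(seed)
    if pairing == "mother_daughter":
        for r in forest.records:
            if r.end_fate != FATE_DIVIDED or r.is_sop:
                continue
            for kid in kids.get(r.cell_id, []):
                if kid.end_fate == FATE_DIVIDED and not kid.is_sop:
                    xs.append(r.cycle_time)
                    ys.append(kid.cycle_time)
    elif pairing == "sister":
        for r in forest.records:
            pair = [k for k in kids.get(r.cell_id, [])
                    if k.end_fate == FATE_DIVIDED and not k.is_sop]
            if len(pair) == 2:
                a, b = sorted(pair, key=lambda c: c.cell_id)
                if rng.random() < 0.5:
                    a, b = b, a
                xs.append(a.cycle_time)
                ys.append(b.cycle_time)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    return np.asarray(xs), np.asarray(ys)


def pair_correlations(forest: LineageForest, pairing: str,
                      seed: int = 0) -> CorrelationResult:
    """Pearson / Spearman correlation of cycle-time pairs (see
    :func:`cycle_time_pairs` for the pairing conventions)."""
    x, y = cycle_time_pairs(forest, pairing, seed=seed)
    if x.size < 2:
        raise InsufficientDataError(f"only {x.size} complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return CorrelationResult(
        pairing=pairing,
        pearson=float(sstats.pearsonr(x, y).statistic),
        spearman=float(sstats.spearmanr(x, y).statistic),
        n_pairs=int(x.size),
    )


# ---------------------------------------------------------------------------
# arrest analysis

def label_arrested(forest: LineageForest,
                   min_followup: float = 0.0) -> LineageForest:
    """Flag arrested cells in place and return the forest.

    A cell is arrested iff it is censored at the end of the movie, is not
    an SOP and was not extruded; divided cells are never arrested.  With
    ``min_followup > 0``, censored cells born within that margin of
    ``movie_end`` are left unlabelled (None) instead.
    """
    for r in forest.records:
        if r.end_fate == FATE_CENSORED and not r.is_sop:
            if (min_followup > 0 and
                    forest.movie_end - r.birth_time < min_followup):
                r.arrested = None
            else:
                r.arrested = True
        else:
            r.arrested = False
    return forest


def arrest_probabilities(forest: LineageForest, bin_width: float = 1.0,
                         fit: bool = True):
    """Empirical p(t), alpha(t) per division-time bin and a Hill fit.

    Returns ``(table, schedule_or_None)`` where table is a DataFrame with
    columns ``t_mid, n_div, n_ge1, n_eq2, p_hat, alpha_hat`` and the
    schedule holds the weighted-least-squares Hill fits (None on fit
    failure, flagged via the ``fit_failed`` attribute on the table).
    """
    import pandas as pd
    kids = forest.children_map()
    rows = []
    for r in forest.records:
        if r.end_fate != FATE_DIVIDED:
            continue
        daughters = kids.get(r.cell_id, [])
        n_arr = sum(1 for d in daughters if d.arrested)
        rows.append((r.end_time, n_arr))
    if not rows:
        raise InsufficientDataError("no divisions in forest")
    times = np.array([t for t, _ in rows])
    narr = np.array([k for _, k in rows])
    # left-closed right-open bins anchored at integer hAPF
    lo = math.floor(times.min())
    hi = math.ceil(times.max() + 1e-9)
    edges = np.arange(lo, hi + bin_width, bin_width)
    idx = np.digitize(times, edges) - 1
    recs = []
    for b in range(len(edges) - 1):
        m = idx == b
        n_div = int(m.sum())
        if n_div == 0:
            continue
        n_ge1 = int((narr[m] >= 1).sum())
        n_eq2 = int((narr[m] == 2).sum())
        # abscissa = mean division time in the bin: under exponential
        # growth events crowd the late side, so midpoints bias the fit
        recs.append({
            "t_mid": float(times[m].mean()),
            "n_div": n_div, "n_ge1": n_ge1, "n_eq2": n_eq2,
            "p_hat": n_ge1 / n_div,
            "alpha_hat": n_eq2 / n_ge1 if n_ge1 else np.nan,
        })
    table = pd.DataFrame(recs)
    schedule = None
    table.attrs["fit_failed"] = False
    if fit:
        try:
            p_par = _fit_hill(table["t_mid"].values, table["p_hat"].values,
                              table["n_div"].values)
            am = table["n_ge1"].values > 0
            a_par = _fit_hill(table["t_mid"].values[am],
                              table["alpha_hat"].values[am],
                              table["n_ge1"].values[am])
            schedule = ArrestSchedule(p_half_time=p_par[0], p_exponent=p_par[1],
                                      p_plateau=p_par[2],
                                      alpha_half_time=a_par[0],
                                      alpha_exponent=a_par[1],
                                      alpha_plateau=a_par[2])
        except (RuntimeError, ValueError, InsufficientDataError):
            table.attrs["fit_failed"] = True
    return table, schedule


def _fit_hill(t, y, weights):
    if len(t) < 3:
        raise InsufficientDataError("need >= 3 bins for a Hill fit")
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    w = np.sqrt(np.asarray(weights, float))

    def resid(params):
        t_half, logn, plateau = params
        return w * (hill(t, t_half, math.exp(logn), plateau) - y)

    t0 = float(np.interp(0.5 * max(y.max(), 1e-9), y, t)) if y.max() > 0 else t.mean()
    best = None
    for logn0 in (math.log(4), math.log(12), math.log(40)):
        sol = optimize.least_squares(
            resid, x0=[t0, logn0, min(max(y.max(), 0.05), 1.0)],
            bounds=([t.min() - 10, math.log(0.5), 0.0],
                    [t.max() + 10, math.log(400), 1.0]))
        if best is None or sol.cost < best.cost:
            best = sol
    t_half, logn, plateau = best.x
    return float(t_half), float(math.exp(logn)), float(plateau)


def fraction_arrested_created(forest: LineageForest, bin_width: float = 1.0):
    """Per birth-time bin, the fraction of newborn (non-founder) cells
    flagged arrested.  Returns a DataFrame ``t_mid, n_born, n_arrested,
    fraction``."""
    import pandas as pd
    born = [(r.birth_time, bool(r.arrested)) for r in forest.records
            if r.parent_id is not None]
    if not born:
        raise InsufficientDataError("no newborn cells")
    times = np.array([t for t, _ in born])
    arr = np.array([a for _, a in born])
    lo = math.floor(times.min())
    edges = np.arange(lo, math.ceil(times.max() + 1e-9) + bin_width, bin_width)
    idx = np.digitize(times, edges) - 1
    recs = []
    for b in range(len(edges) - 1):
        m = idx == b
        if not m.any():
            continue
        recs.append({"t_mid": 0.5 * (edges[b] + edges[b + 1]),
                     "n_born": int(m.sum()),
                     "n_arrested": int(arr[m].sum()),
                     "fraction": float(arr[m].mean())})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# binned relations and spatial correlation

def binned_relation(x, y, n_bins: int = 8, mode: str = "equal_count"):
    """Bin y against x; per bin return (mean x, mean y, SEM y, n).

    ``mode`` is "equal_count" (quantile edges) or "equal_width".
    SEM = sd/sqrt(n) with the sample sd (0 for singleton bins).
    """
    import pandas as pd
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or x.size != y.size:
        raise ValueError("x and y must be equal-length and non-empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if mode == "equal_count":
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
    elif mode == "equal_width":
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    edges[-1] = np.nextafter(edges[-1], np.inf)
    idx = np.digitize(x, edges) - 1
    recs = []
    for b in range(len(edges) - 1):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            continue
        sem = float(y[m].std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        recs.append({"x_mean": float(x[m].mean()),
                     "y_mean": float(y[m].mean()),
                     "y_sem": sem, "n": n})
    return pd.DataFrame(recs)


def neighbor_cycle_correlation(forest: LineageForest) -> CorrelationResult:
    """Correlation between a divided cell's cycle time and that of its
    nearest neighbor (centroid distance at birth) among cells alive at
    its birth with a complete cycle.  Ties break to the lowest cell_id."""
    cells = []
    for r in forest.records:
        if r.end_fate != FATE_DIVIDED or r.is_sop or not r.centroid_series:
            continue
        t0, x0, y0 = min(r.centroid_series, key=lambda c: c[0])
        cells.append((r, x0, y0))
    if len(cells) < 2:
        raise InsufficientDataError("need >= 2 cells with centroids")
    xs, ys = [], []
    for r, x0, y0 in cells:
        best = None
        for q, xq, yq in cells:
            if q.cell_id == r.cell_id or not q.alive_at(r.birth_time):
                continue
            d = math.hypot(x0 - xq, y0 - yq)
            key = (d, q.cell_id)
            if best is None or key < best[0]:
                best = (key, q)
        if best is not None:
            xs.append(r.cycle_time)
            ys.append(best[1].cycle_time)
    if len(xs) < 2:
        raise InsufficientDataError("fewer than 2 contemporaneous pairs")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return CorrelationResult(
        pairing="nearest_neighbor",
        pearson=float(sstats.pearsonr(x, y).statistic),
        spearman=float(sstats.spearmanr(x, y).statistic),
        n_pairs=int(x.size),
    )
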