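"""Event-driven stochastic simulation of histoblast population growth.

The model: each cell draws its cycle time at birth.  Sister cells draw
their cycle times as one correlated bivariate-normal pair whose mean
depends on the birth time (cleavage phase, pause span, expansion cubic),
whose coefficient of variation is fixed per phase, and whose correlation
coefficient reproduces the measured sister-sister cycle-time correlation.
Divisions falling inside the proliferation pause are deferred to the end
of the pause (cells keep ageing, so all overdue cells divide together in
a burst).  At each division the pair of daughters is classified through
the time-dependent arrest probabilities p(t) and alpha(t) — no arrested
daughter, one, or both — and non-arrested newborns inside the SOP window
become sensory-organ precursors with a fixed probability.  Arrested
cells and SOPs persist without dividing; at the end of the run all
survivors are censored.

Times are hours APF throughout.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .lineage import (FATE_CENSORED, FATE_DIVIDED, CellTrackRecord,
                      LineageForest)
from .stats import ArrestSchedule

__all__ = ["SimConfig", "SimResult", "default_config",
           "draw_sister_cycle_times", "simulate", "class_counts",
           "cycle_time_mean", "DEFAULT_EXPANSION_CUBIC"]

# Mean expansion cycle time (h) as a cubic in birth time t (hAPF),
# lowest-order coefficient first.  Calibrated once so that the value at
# the end of the pause is ~4.3 h (the expansion starting value, also used
# throughout the 3.3-14.7 hAPF span), the 15-28 hAPF average is ~4.5 h,
# and the curve has a shallow dip near 21-22 hAPF; frozen thereafter.
DEFAULT_EXPANSION_CUBIC = (-5.773894729390386, 1.5228603609658182,
                           -0.07485818675746965, 0.001216409577268754)


@dataclass
class SimConfig:
    """Full parameterization of a growth-simulation run."""

    n_init: int = 16
    t_start: float = 0.0
    t_end: float = 33.0
    cleavage_end: float = 3.3       # birth-time boundary of the cleavage law
    pause_start: float = 12.5
    pause_end: float = 14.7
    cleavage_mean: float = 2.7      # h
    cleavage_cv: float = 0.10
    expansion_mean_curve: tuple = DEFAULT_EXPANSION_CUBIC
    expansion_cv: float = 0.22
    sister_rho: float = 0.55
    arrest: ArrestSchedule = field(default_factory=lambda: ArrestSchedule(
        p_half_time=26.0, p_exponent=40.0, p_plateau=1.0,
        alpha_half_time=26.5, alpha_exponent=40.0, alpha_plateau=1.0))
    sop_prob: float = 0.02
    sop_window: tuple = (20.0, 26.0)
    min_cycle: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_start < self.cleavage_end < self.pause_start
                < self.pause_end < self.t_end):
            raise ValueError("phase boundaries must be ordered "
                             "t_start < cleavage_end < pause_start "
                             "< pause_end < t_end")
        if self.cleavage_cv <= 0 or self.expansion_cv <= 0:
            raise ValueError("cvs must be > 0")
        if not -1.0 < self.sister_rho < 1.0:
            raise ValueError("|sister_rho| must be < 1")
        if not 0.0 <= self.sop_prob <= 1.0:
            raise ValueError("sop_prob outside [0, 1]")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        if "arrest" in d and isinstance(d["arrest"], dict):
            d["arrest"] = ArrestSchedule(**d["arrest"])
        for key in ("expansion_mean_curve", "sop_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimResult:
    forest: LineageForest
    config: SimConfig


def default_config(**overrides) -> SimConfig:
    """The base case: anterior-nest founders with the measured phase
    boundaries, cycle-time statistics and arrest schedule."""
    return SimConfig(**overrides)


def cycle_time_mean(t_birth: float, config: SimConfig) -> float:
    """Mean cycle time for a cell born at ``t_birth``.

    Cleavage law before ``cleavage_end``; between the cleavage end and
    the pause end, the expansion-phase starting value (the cubic
    evaluated at ``pause_end``); the cubic itself afterwards.
    """
    c = config.expansion_mean_curve
    if t_birth < config.cleavage_end:
        return config.cleavage_mean
    t_eff = max(t_birth, config.pause_end)
    return float(sum(coef * t_eff ** k for k, coef in enumerate(c)))


def _cv_at(t_birth: float, config: SimConfig) -> float:
    return (config.cleavage_cv if t_birth < config.cleavage_end
            else config.expansion_cv)


def draw_sister_cycle_times(mean: float, cv: float, rho: float,
                            rng: np.random.Generator,
                            min_cycle: float = 0.5,
                            max_redraws: int = 1000) -> tuple[float, float]:
    """Draw one correlated sister pair of cycle times.

    The pair comes from a bivariate normal with identical marginals
    N(mean, (cv*mean)^2) and correlation ``rho``; the whole pair is
    redrawn whenever either component falls below ``min_cycle`` (so the
    correlation structure is preserved rather than clipped).
    """
    if mean <= 0 or cv <= 0:
        raise ValueError("mean and cv must be > 0")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    sd = cv * mean
    # Cholesky of [[1, rho], [rho, 1]]
    b = math.sqrt(max(0.0, 1.0 - rho * rho))
    for _ in range(max_redraws):
        z1, z2 = rng.standard_normal(2)
        t1 = mean + sd * z1
        t2 = mean + sd * (rho * z1 + b * z2)
        if t1 >= min_cycle and t2 >= min_cycle:
            return float(t1), float(t2)
    raise RuntimeError(
        f"redraw cap {max_redraws} exceeded (mean={mean}, cv={cv}): "
        "degenerate parameters")


def _apply_pause(t_div: float, config: SimConfig) -> float:
    """Defer divisions scheduled inside the pause window to its end."""
    if config.pause_start <= t_div < config.pause_end:
        return config.pause_end
    return t_div


def simulate(config: SimConfig) -> SimResult:
    """Run the event-driven growth simulation.

    Founders draw independent cycle times from the distribution at
    ``t_start``.  Events are processed in (time, cell index) order so a
    given (config, seed) reproduces bitwise-identically.
    """
    rng = np.random.default_rng(config.seed)
    records: list[CellTrackRecord] = []
    # heap of (division_time, insertion order, record index)
    heap: list[tuple[float, int]] = []
    counter = 0

    def new_cell(parent_id, birth, cycle, arrested, is_sop):
        nonlocal counter
        cid = f"c{counter:06d}"
        counter += 1
        rec = CellTrackRecord(cell_id=cid, parent_id=parent_id,
                              birth_time=birth, end_time=math.nan,
                              end_fate=FATE_CENSORED, is_sop=is_sop,
                              arrested=arrested)
        records.append(rec)
        if not arrested and not is_sop:
            t_div = _apply_pause(birth + cycle, config)
            if t_div < config.t_end:
                rec.end_time = t_div
                rec.end_fate = FATE_DIVIDED
                heapq.heappush(heap, (t_div, len(records) - 1))
                return rec
        rec.end_time = config.t_end
        return rec

    for _ in range(config.n_init):
        mean = cycle_time_mean(config.t_start, config)
        cv = _cv_at(config.t_start, config)
        t1, _t2 = draw_sister_cycle_times(mean, cv, config.sister_rho, rng,
                                          config.min_cycle)
        new_cell(None, config.t_start, t1, False, False)

    while heap:
        t_div, idx = heapq.heappop(heap)
        mother = records[idx]
        # daughters: correlated cycle-time pair drawn at birth time t_div
        mean = cycle_time_mean(t_div, config)
        cv = _cv_at(t_div, config)
        c1, c2 = draw_sister_cycle_times(mean, cv, config.sister_rho, rng,
                                         config.min_cycle)
        p = float(config.arrest.p(t_div))
        arrested1 = arrested2 = False
        if rng.random() < p:
            alpha = float(config.arrest.alpha(t_div))
            if rng.random() < alpha:
                arrested1 = arrested2 = True
            elif rng.random() < 0.5:
                arrested1 = True
            else:
                arrested2 = True
        for cyc, arr in ((c1, arrested1), (c2, arrested2)):
            is_sop = False
            if (not arr and config.sop_prob > 0
                    and config.sop_window[0] <= t_div < config.sop_window[1]):
                is_sop = rng.random() < config.sop_prob
            new_cell(mother.cell_id, t_div, cyc, arr, is_sop)

    forest = LineageForest(records=records, movie_end=config.t_end,
                           roi_label="simulated")
    return SimResult(forest=forest, config=config)


def class_counts(result: SimResult, grid_step: float = 0.25,
                 normalize_at: Optional[float] = None):
    """Counts of cycling / arrested / SOP / total cells on a time grid.

    ``normalize_at`` divides every series by the total count at that
    time (must lie inside the run).  Totals always equal the sum of the
    three classes.
    """
    import pandas as pd
    cfg = result.config
    times = np.arange(cfg.t_start, cfg.t_end + 1e-9, grid_step)
    recs = result.forest.records
    birth = np.array([r.birth_time for r in recs])
    end = np.array([r.end_time for r in recs])
    is_sop = np.array([r.is_sop for r in recs])
    arrested = np.array([bool(r.arrested) for r in recs])
    rows = []
    for t in times:
        # censored survivors count as alive at the final grid point
        alive = (birth <= t) & ((end > t) | ((end == cfg.t_end) & (t == cfg.t_end)))
        n_sop = int((alive & is_sop).sum())
        n_arr = int((alive & arrested & ~is_sop).sum())
        n_tot = int(alive.sum())
        rows.append({"t": t, "cycling": n_tot - n_arr - n_sop,
                     "arrested": n_arr, "sop": n_sop, "total": n_tot})
    df = pd.DataFrame(rows)
    if normalize_at is not None:
        if not (cfg.t_start <= normalize_at <= cfg.t_end):
            raise ValueError("normalize_at outside the simulated range")
        ref = float(np.interp(normalize_at, df["t"], df["total"]))
        if ref <= 0:
            raise ValueError("total count at normalization time is zero")
        for col in ("cycling", "arrested", "sop", "total"):
            df[col] = df[col] / ref
    return df
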