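"""Fluorescence-intensity bookkeeping: junction-angle binning of Myo II,
ECM intensity normalizations, and FUCCI cell-cycle phase calling.

All normalizations are invariant under a global rescaling of the raw
intensities (camera gain).  Junction angles are measured from the DV
axis and folded into [0, 90] degrees (a junction is axial, not
directed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["JunctionMeasurement", "FucciRecord", "bin_junction_intensity",
           "normalize_prepupal_ecm", "normalize_pupal_ecm",
           "fucci_total_series", "fucci_phase_call",
           "PHASE_G1", "PHASE_S", "PHASE_G2M", "PHASE_UNCLASSIFIED"]

PHASE_G1 = "G1"
PHASE_S = "S"
PHASE_G2M = "G2M"
PHASE_UNCLASSIFIED = "unclassified"


@dataclass
class JunctionMeasurement:
    junction_id: str
    angle_deg: float          # [0, 90], from the DV axis
    length_um: float
    mean_intensity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg <= 90.0:
            raise ValueError("angle must lie in [0, 90] degrees")
        if self.length_um <= 0:
            raise ValueError("length must be > 0")
        if self.mean_intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass
class FucciRecord:
    nucleus_id: str
    t: float                  # hAPF
    gfp: float                # GFP-E2F1, a.u.
    rfp: float                # RFP-CycB, a.u.
    phase: Optional[str] = None


def bin_junction_intensity(junctions: Sequence[JunctionMeasurement],
                           bin_width: float = 5.0) -> pd.DataFrame:
    """Median and interquartile range of junction intensity per angle bin.

    Bins are [0, w), [w, 2w), ..., with the final bin closed at 90 so an
    exactly-DV-orthogonal junction is counted.  Quantiles use linear
    interpolation.  Empty bins are reported with n = 0 and NaN summary.
    """
    if len(junctions) == 0:
        raise ValueError("no junctions supplied")
    angles = np.array([j.angle_deg for j in junctions])
    intens = np.array([j.mean_intensity for j in junctions])
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    idx = np.minimum(np.digitize(angles, edges) - 1, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        m = idx == b
        if m.any():
            q1, med, q3 = np.percentile(intens[m], [25, 50, 75])
            rows.append({"angle_mid": 0.5 * (edges[b] + edges[b + 1]),
                         "median": med, "iqr": q3 - q1, "n": int(m.sum())})
        else:
            rows.append({"angle_mid": 0.5 * (edges[b] + edges[b + 1]),
                         "median": np.nan, "iqr": np.nan, "n": 0})
    return pd.DataFrame(rows)


def normalize_prepupal_ecm(series: pd.DataFrame, t_ref: float = 13.0,
                           max_gap: Optional[float] = None) -> pd.DataFrame:
    """Divide an ECM intensity time course by its value at the reference
    time (13 hAPF, once head eversion is complete).

    ``series`` has columns ``t`` and ``intensity``; the sample nearest
    ``t_ref`` is used, required to lie within half a frame interval
    (or ``max_gap`` when given).  Idempotent: renormalizing a normalized
    series leaves it unchanged.
    """
    t = np.asarray(series["t"], float)
    y = np.asarray(series["intensity"], float)
    i = int(np.argmin(np.abs(t - t_ref)))
    if max_gap is None:
        dt = np.min(np.diff(np.sort(t))) if t.size > 1 else 0.0
        max_gap = 0.5 * dt
    if abs(t[i] - t_ref) > max_gap + 1e-12:
        raise ValueError(f"no sample within {max_gap} h of t={t_ref}")
    ref = y[i]
    if ref == 0:
        raise ValueError("reference intensity at t_ref is zero")
    return pd.DataFrame({"t": t, "intensity": y / ref})


def normalize_pupal_ecm(series_lec: pd.DataFrame,
                        series_hist: pd.DataFrame,
                        n_lowest: int = 5,
                        mode: str = "subtract_then_scale"
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Background-correct pupal ECM intensities under LECs and histoblasts.

    The background B is the mean of the ``n_lowest`` frames with the
    lowest intensity under the LECs.  Default convention
    (``subtract_then_scale``): both series are shifted by -B and scaled
    by one common factor so the first LEC value maps to 1 (the LEC
    series then runs from 1 down to ~0).  The alternative reading,
    dividing the shifted series by B, is available as
    ``mode="subtract_then_divide_by_background"``.
    """
    lec_t = np.asarray(series_lec["t"], float)
    lec_y = np.asarray(series_lec["intensity"], float)
    hist_t = np.asarray(series_hist["t"], float)
    hist_y = np.asarray(series_hist["intensity"], float)
    if lec_y.size < n_lowest:
        raise ValueError(f"need >= {n_lowest} LEC frames")
    b = float(np.sort(lec_y)[:n_lowest].mean())
    if mode == "subtract_then_scale":
        scale = lec_y[0] - b
        if scale == 0:
            raise ValueError("first LEC frame equals the background")
    elif mode == "subtract_then_divide_by_background":
        if b == 0:
            raise ValueError("zero background")
        scale = b
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return (pd.DataFrame({"t": lec_t, "intensity": (lec_y - b) / scale}),
            pd.DataFrame({"t": hist_t, "intensity": (hist_y - b) / scale}))


def fucci_total_series(records: Sequence[FucciRecord]) -> pd.DataFrame:
    """Per-frame total intensity of each FUCCI channel, normalized to
    the first frame (both channels start at 1)."""
    if len(records) == 0:
        raise ValueError("no records")
    df = pd.DataFrame([{"t": r.t, "gfp": r.gfp, "rfp": r.rfp}
                       for r in records])
    tot = df.groupby("t", sort=True).sum().reset_index()
    if tot.loc[0, "gfp"] == 0 or tot.loc[0, "rfp"] == 0:
        raise ValueError("zero total intensity in the first frame")
    tot["gfp"] = tot["gfp"] / tot.loc[0, "gfp"]
    tot["rfp"] = tot["rfp"] / tot.loc[0, "rfp"]
    return tot


def fucci_phase_call(records: Sequence[FucciRecord],
                     thresholds: tuple[float, float] = (0.5, 2.0)
                     ) -> list[FucciRecord]:
    """Assign a cell-cycle phase to every nucleus of one frame.

    Each channel is normalized to its mean over the nuclei; the ratio
    r = normalized RFP / normalized GFP is thresholded: r < low -> G1
    (GFP-E2F1 only), r > high -> S (RFP-CycB dominant), in between ->
    G2M (both markers).  The call depends only on the ratio, so it is
    invariant under per-channel gain.  Nuclei dark in both channels are
    unclassified.

    Caveat: the per-channel mean normalization makes the call relative
    to the frame's population.  For a perfectly homogeneous population
    every ratio is ~1 and everything lands in the mid band; the call is
    only meaningful when the frame mixes cell-cycle states (as real
    frames do).
    """
    if len(records) < 2:
        raise ValueError("need >= 2 nuclei for mean normalization")
    lo, hi = thresholds
    if not 0 < lo < hi:
        raise ValueError("thresholds must satisfy 0 < low < high")
    gfp = np.array([r.gfp for r in records], float)
    rfp = np.array([r.rfp for r in records], float)
    gmean, rmean = gfp.mean(), rfp.mean()
    if gmean == 0 or rmean == 0:
        raise ValueError("a channel is entirely dark")
    out = []
    for rec, g, f in zip(records, gfp / gmean, rfp / rmean):
        if g == 0 and f == 0:
            phase = PHASE_UNCLASSIFIED
        elif g == 0:
            phase = PHASE_S
        else:
            ratio = f / g
            phase = (PHASE_G1 if ratio < lo else
                     PHASE_S if ratio > hi else PHASE_G2M)
        out.append(FucciRecord(nucleus_id=rec.nucleus_id, t=rec.t,
                               gfp=rec.gfp, rfp=rec.rfp, phase=phase))
    return out
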