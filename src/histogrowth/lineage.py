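"""Lineage containers for tracked histoblasts.

A :class:`LineageForest` holds the complete division history of a tracked
cell population: each :class:`CellTrackRecord` is one cell from its birth
(either the start of the movie for founders, or its mother's division) to
its end (division, extrusion, or censoring at the end of the movie).
Times are in hours after puparium formation (hAPF), apical areas in
square microns, centroid coordinates in microns with x along the
anterior-posterior (AP) axis and y along the dorsal-ventral (DV) axis.

The on-disk format is a plain tab-separated table (one row per cell)
optionally accompanied by long-format companion tables carrying per-frame
area / elongation / centroid samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "CellTrackRecord",
    "LineageForest",
    "LineageValidationError",
    "FATE_DIVIDED",
    "FATE_EXTRUDED",
    "FATE_CENSORED",
    "read_tracks",
    "write_tracks",
]

FATE_DIVIDED = "divided"
FATE_EXTRUDED = "extruded"
FATE_CENSORED = "censored"
_FATES = (FATE_DIVIDED, FATE_EXTRUDED, FATE_CENSORED)

# Tolerance (h) allowed between a mother's end time and a daughter's birth
# time; one movie frame is 2.5 min ~= 0.042 h.
FRAME_TOL = 0.05


class LineageValidationError(ValueError):
    """Raised when a tracked-cell table violates a forest invariant."""


@dataclass
class CellTrackRecord:
    """One tracked cell: identity, lineage link, life span and fate."""

    cell_id: str
    parent_id: Optional[str]
    birth_time: float
    end_time: float
    end_fate: str
    is_sop: bool = False
    arrested: Optional[bool] = None
    area_series: Optional[Sequence[tuple[float, float]]] = None
    elongation_series: Optional[Sequence[tuple[float, float]]] = None
    centroid_series: Optional[Sequence[tuple[float, float, float]]] = None

    @property
    def cycle_time(self) -> float:
        return self.end_time - self.birth_time

    def alive_at(self, t: float) -> bool:
        """Alive means ``birth_time <= t < end_time``."""
        return self.birth_time <= t < self.end_time


@dataclass
class LineageForest:
    """A forest of cell tracks plus movie metadata."""

    records: list[CellTrackRecord]
    movie_end: float
    roi_label: str = "noborder"
    _by_id: dict[str, CellTrackRecord] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self._by_id = {r.cell_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, cell_id: str) -> CellTrackRecord:
        return self._by_id[cell_id]

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self._by_id

    def children(self, cell_id: str) -> list[CellTrackRecord]:
        return [r for r in self.records if r.parent_id == cell_id]

    def children_map(self) -> dict[str, list[CellTrackRecord]]:
        out: dict[str, list[CellTrackRecord]] = {}
        for r in self.records:
            if r.parent_id is not None:
                out.setdefault(r.parent_id, []).append(r)
        return out

    def founders(self) -> list[CellTrackRecord]:
        return [r for r in self.records if r.parent_id is None]

    def alive_count(self, t: float) -> int:
        return sum(r.alive_at(t) for r in self.records)

    def validate(self) -> None:
        """Check all forest invariants; raise naming the first offender."""
        seen: set[str] = set()
        for r in self.records:
            if r.cell_id in seen:
                raise LineageValidationError(f"duplicate cell_id {r.cell_id!r}")
            seen.add(r.cell_id)
        children = self.children_map()
        for r in self.records:
            if r.end_fate not in _FATES:
                raise LineageValidationError(
                    f"cell {r.cell_id!r}: unknown fate {r.end_fate!r}"
                )
            if not (r.birth_time < r.end_time):
                raise LineageValidationError(
                    f"cell {r.cell_id!r}: non-positive duration "
                    f"({r.birth_time} -> {r.end_time})"
                )
            if r.parent_id is not None and r.parent_id not in self._by_id:
                raise LineageValidationError(
                    f"cell {r.cell_id!r}: parent {r.parent_id!r} missing from table"
                )
            kids = children.get(r.cell_id, [])
            if r.end_fate == FATE_DIVIDED:
                if len(kids) != 2:
                    raise LineageValidationError(
                        f"cell {r.cell_id!r}: divided but has {len(kids)} children"
                    )
                for kid in kids:
                    if abs(kid.birth_time - r.end_time) > FRAME_TOL:
                        raise LineageValidationError(
                            f"cell {kid.cell_id!r}: birth {kid.birth_time} does not "
                            f"match mother {r.cell_id!r} division at {r.end_time}"
                        )
            elif kids:
                raise LineageValidationError(
                    f"cell {r.cell_id!r}: fate {r.end_fate} but has children"
                )
            if r.end_time > self.movie_end + FRAME_TOL:
                raise LineageValidationError(
                    f"cell {r.cell_id!r}: end_time {r.end_time} beyond movie_end "
                    f"{self.movie_end}"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Parent links with strictly increasing birth times cannot form a
        # cycle, but tables edited by hand can; walk up with a visited set.
        for r in self.records:
            seen = {r.cell_id}
            cur = r
            while cur.parent_id is not None:
                if cur.parent_id in seen:
                    raise LineageValidationError(
                        f"cycle in parent links reached from {r.cell_id!r}"
                    )
                seen.add(cur.parent_id)
                cur = self._by_id[cur.parent_id]

    def relabelled(self, **kwargs) -> "LineageForest":
        return LineageForest(records=list(self.records),
                             movie_end=self.movie_end,
                             roi_label=self.roi_label, **kwargs)


_COLUMNS = ["cell_id", "parent_id", "birth_t", "end_t", "fate", "is_sop"]


def read_tracks(path, area_path=None, centroid_path=None,
                movie_end: Optional[float] = None,
                roi_label: str = "noborder") -> LineageForest:
    """Read a tracked-cell TSV (plus optional companion tables).

    The main table has columns ``cell_id, parent_id, birth_t, end_t, fate,
    is_sop``; an empty / NA ``parent_id`` marks a founder.  Companion
    tables are long format: ``cell_id, t, area`` and ``cell_id, t, x, y``.
    The returned forest is validated; violations raise
    :class:`LineageValidationError` naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"cell_id": str, "parent_id": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise LineageValidationError(f"{path}: missing columns {missing}")
    areas: dict[str, list[tuple[float, float]]] = {}
    if area_path is not None:
        adf = pd.read_csv(area_path, sep="\t", float_precision="round_trip",
                          dtype={"cell_id": str})
        for cid, grp in adf.groupby("cell_id"):
            areas[cid] = list(zip(grp["t"], grp["area"]))
    cents: dict[str, list[tuple[float, float, float]]] = {}
    if centroid_path is not None:
        cdf = pd.read_csv(centroid_path, sep="\t", float_precision="round_trip",
                          dtype={"cell_id": str})
        for cid, grp in cdf.groupby("cell_id"):
            cents[cid] = list(zip(grp["t"], grp["x"], grp["y"]))
    records = []
    for row in df.itertuples(index=False):
        pid = row.parent_id
        if pid is None or (isinstance(pid, float) and math.isnan(pid)) or pid == "":
            pid = None
        records.append(CellTrackRecord(
            cell_id=str(row.cell_id),
            parent_id=pid,
            birth_time=float(row.birth_t),
            end_time=float(row.end_t),
            end_fate=str(row.fate),
            is_sop=bool(int(row.is_sop)),
            area_series=areas.get(str(row.cell_id)),
            centroid_series=cents.get(str(row.cell_id)),
        ))
    if movie_end is None:
        movie_end = max(r.end_time for r in records)
    forest = LineageForest(records=records, movie_end=movie_end,
                           roi_label=roi_label)
    forest.validate()
    return forest


def write_tracks(forest: LineageForest, path, area_path=None,
                 centroid_path=None) -> None:
    """Write a forest back to the tracks TSV schema (round-trips with
    :func:`read_tracks`)."""
    rows = [{
        "cell_id": r.cell_id,
        "parent_id": "" if r.parent_id is None else r.parent_id,
        "birth_t": repr(r.birth_time),
        "end_t": repr(r.end_time),
        "fate": r.end_fate,
        "is_sop": int(r.is_sop),
    } for r in forest.records]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
    if area_path is not None:
        arows = [
            {"cell_id": r.cell_id, "t": repr(t), "area": repr(a)}
            for r in forest.records if r.area_series
            for (t, a) in r.area_series
        ]
        pd.DataFrame(arows, columns=["cell_id", "t", "area"]).to_csv(
            area_path, sep="\t", index=False)
    if centroid_path is not None:
        crows = [
            {"cell_id": r.cell_id, "t": repr(t), "x": repr(x), "y": repr(y)}
            for r in forest.records if r.centroid_series
            for (t, x, y) in r.centroid_series
        ]
        pd.DataFrame(crows, columns=["cell_id", "t", "x", "y"]).to_csv(
            centroid_path, sep="\t", index=False)
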