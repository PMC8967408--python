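"""Synthetic input generators.

Every table the analysis consumes can be generated here with the
statistical structure the analyses assume, so the full pipeline is
exercisable without any microscopy data: lineage forests with per-frame
geometry, post-ablation deformation fields (forward continuum solve plus
noise), FUCCI nucleus intensities with known class fractions, exponential
recoil time series, and junction-angle intensity tables.  All generators
are deterministic given (config, seed) and emit their ground truth
alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .continuum import (ContinuumParams, DeformationField, solve_disc,
                        sunflower_points)
from .intensity import FucciRecord, JunctionMeasurement
from .lineage import FATE_DIVIDED
from .sim import SimConfig, SimResult, simulate

__all__ = ["NoiseSpec", "gen_forest", "gen_deformation", "gen_fucci",
           "gen_ablation_series", "gen_junctions", "FUCCI_PRESETS"]


@dataclass
class NoiseSpec:
    """Additive or multiplicative Gaussian noise."""

    kind: str = "gaussian_additive"    # or "gaussian_multiplicative"
    sigma: float = 0.0
    seed: int = 0

    def apply(self, values: np.ndarray,
              rng: Optional[np.random.Generator] = None) -> np.ndarray:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.sigma == 0:
            return np.asarray(values, float).copy()
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        noise = rng.normal(0.0, self.sigma, size=np.shape(values))
        if self.kind == "gaussian_additive":
            return values + noise
        if self.kind == "gaussian_multiplicative":
            return values * (1.0 + noise)
        raise ValueError(f"unknown noise kind {self.kind!r}")


# ---------------------------------------------------------------------------
# lineage forests with geometry

def gen_forest(config: SimConfig, geometry: bool = False,
               frame_step: float = 0.5, area_set_point: float = 15.0,
               relax_rate: float = 0.4, jitter: float = 0.5
               ) -> SimResult:
    """Simulated lineage forest, optionally with per-frame areas and
    centroids.

    The area model is a bookkeeping fixture, not mechanics: each
    daughter takes half its mother's final area (so areas are conserved
    across a division) and relaxes exponentially toward a set point
    (default 15 um^2) at ``relax_rate`` per hour.  Centroids sit on a
    jittered hexagonal packing assigned at birth and inherited near the
    mother, enough structure for nearest-neighbor statistics.
    """
    result = simulate(config)
    if not geometry:
        return result
    rng = np.random.default_rng(config.seed + 1)
    forest = result.forest
    # one shared frame grid: every cell present at a frame carries an
    # area there, which is what the growth decomposition requires
    grid = np.arange(config.t_start, config.t_end + 1e-9, frame_step)
    if grid[-1] < config.t_end - 1e-9:
        grid = np.append(grid, config.t_end)
    order = sorted(forest.records, key=lambda r: (r.birth_time, r.cell_id))
    birth_area: dict[str, float] = {}
    positions: dict[str, tuple[float, float]] = {}
    spacing = 2.0 * math.sqrt(area_set_point / math.pi)
    n_side = int(math.ceil(math.sqrt(config.n_init))) + 1
    free = [(spacing * (i + 0.5 * (j % 2)), spacing * j * math.sqrt(3) / 2)
            for j in range(n_side) for i in range(n_side)]
    rng.shuffle(free)

    def area_at(rec, t):
        a0 = birth_area[rec.cell_id]
        return area_set_point + (a0 - area_set_point) * math.exp(
            -relax_rate * (t - rec.birth_time))

    for rec in order:
        if rec.parent_id is None:
            birth_area[rec.cell_id] = area_set_point * float(
                rng.uniform(0.8, 1.2))
            pos = free.pop()
        else:
            mother = forest[rec.parent_id]
            # daughters split the mother's final area exactly in half
            birth_area[rec.cell_id] = 0.5 * area_at(mother, mother.end_time)
            px, py = positions[rec.parent_id]
            pos = (px + float(rng.normal(0, jitter)),
                   py + float(rng.normal(0, jitter)))
        positions[rec.cell_id] = pos
        frames = grid[(grid >= rec.birth_time) & (grid < rec.end_time)]
        if rec.end_fate != FATE_DIVIDED and rec.end_time >= grid[-1] - 1e-9:
            frames = np.append(frames, grid[-1])
        rec.area_series = [(float(t), area_at(rec, t)) for t in frames]
        rec.centroid_series = [(float(t), pos[0], pos[1]) for t in frames]
        if not frames.size:
            # born and gone between two frames: invisible to the frame
            # grid (no area samples), but keep a birth centroid
            rec.area_series = None
            rec.centroid_series = [(rec.birth_time, pos[0], pos[1])]
    return result


# ---------------------------------------------------------------------------
# deformation fields

def gen_deformation(params: ContinuumParams, n_points: int = 200,
                    noise: Optional[NoiseSpec] = None,
                    seed: int = 0) -> DeformationField:
    """Forward continuum solution sampled at quasi-uniform points with
    optional noise on the observables (for fit-recovery tests)."""
    pts = sunflower_points(n_points)
    field = solve_disc(params, points=pts)
    if noise is None or noise.sigma == 0:
        return field
    rng = np.random.default_rng(noise.seed if noise.seed else seed)
    return DeformationField(
        points=field.points,
        displacement=field.displacement,
        area_change=noise.apply(field.area_change, rng),
        exx_minus_eyy=noise.apply(field.exx_minus_eyy, rng),
        exy=noise.apply(field.exy, rng),
        ring_displacement=field.ring_displacement,
    )


# ---------------------------------------------------------------------------
# FUCCI populations

# Class fractions (G1, S, G2M) measured at the two reference stages:
# during the proliferation pause (12 hAPF) cells pile up in G2, while in
# the expansion phase (16 hAPF) G1 dominates.
FUCCI_PRESETS = {
    "12hAPF": {"G1": 0.18, "S": 0.32, "G2M": 0.50},
    "16hAPF": {"G1": 0.44, "S": 0.20, "G2M": 0.36},
}

# class-conditional median intensities (a.u.): GFP-E2F1 marks G1 (and
# G2), RFP-CycB marks S/G2/M; medians separated 8-fold between "on" and
# "off" channels
_CLASS_MEDIANS = {"G1": (8.0, 1.0), "S": (1.0, 8.0), "G2M": (8.0, 8.0)}


def gen_fucci(fractions: dict, n: int, t: float = 12.0,
              sigma_log: float = 0.12, seed: int = 0,
              label_sampling: str = "stratified") -> list[FucciRecord]:
    """Log-normal two-channel nucleus intensities with known phases.

    ``fractions`` maps {"G1", "S", "G2M"} to class probabilities summing
    to 1.  Ground-truth labels are kept on the returned records' .phase
    so classifier recovery can be scored.

    By default the class counts are stratified (largest-remainder
    rounding of ``n * fraction``, order shuffled), so the population
    composition equals the stated fractions exactly and a recovery test
    reads out classification error alone; ``label_sampling="multinomial"``
    draws labels independently instead, adding sampling noise to the
    composition itself.
    """
    keys = ("G1", "S", "G2M")
    probs = np.array([fractions[k] for k in keys], float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    if label_sampling == "stratified":
        ideal = probs * n
        counts = np.floor(ideal).astype(int)
        remainder = ideal - counts
        for i in np.argsort(-remainder)[: n - counts.sum()]:
            counts[i] += 1
        labels = rng.permutation(np.repeat(np.arange(len(keys)), counts))
    elif label_sampling == "multinomial":
        labels = rng.choice(len(keys), size=n, p=probs)
    else:
        raise ValueError(f"unknown label_sampling {label_sampling!r}")
    out = []
    for i, lab in enumerate(labels):
        g_med, r_med = _CLASS_MEDIANS[keys[lab]]
        gfp = float(g_med * math.exp(rng.normal(0.0, sigma_log)))
        rfp = float(r_med * math.exp(rng.normal(0.0, sigma_log)))
        out.append(FucciRecord(nucleus_id=f"n{i:05d}", t=t, gfp=gfp,
                               rfp=rfp, phase=keys[lab]))
    return out


# ---------------------------------------------------------------------------
# recoil series and junction tables

def gen_ablation_series(l0: float, l_inf: float, tau: float, dt: float,
                        n_frames: int, noise: Optional[NoiseSpec] = None
                        ) -> np.ndarray:
    """Kelvin-Voigt exponential relaxation fixture
    ``L(t) = L_inf + (L0 - L_inf) exp(-t/tau)`` plus optional noise."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.arange(n_frames) * dt
    lengths = l_inf + (l0 - l_inf) * np.exp(-t / tau)
    if noise is not None:
        lengths = noise.apply(lengths)
    return lengths


def gen_junctions(profile: Callable[[np.ndarray], np.ndarray], n: int,
                  noise_sigma: float = 0.0, seed: int = 0
                  ) -> list[JunctionMeasurement]:
    """Junction table with angles uniform on [0, 90] degrees and
    intensities from an angular profile plus Gaussian noise."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0.0, 90.0, size=n)
    intens = np.asarray(profile(angles), float)
    if noise_sigma > 0:
        intens = intens + rng.normal(0.0, noise_sigma, size=n)
    intens = np.clip(intens, 0.0, None)
    lengths = rng.uniform(1.0, 5.0, size=n)
    return [JunctionMeasurement(junction_id=f"j{i:05d}",
                                angle_deg=float(a), length_um=float(le),
                                mean_intensity=float(iv))
            for i, (a, le, iv) in enumerate(zip(angles, lengths, intens))]
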