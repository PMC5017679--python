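"""Winter track count survey design: triangular transects and crossings.

Transects are 12-km equilateral triangles (4-km sides).  Each surveyed
transect-year gets a random counting day in the 60-day season; the count
``X_it`` is the number of intersections between the last 24 hours of animal
movement and the triangle edges, each intersection contributing the group
size of the crossing agent.  Survey effort is the habitat-weighted,
in-domain perimeter length ``M_it`` with offset
``e_it = (2/pi) E[L] M_it D_it``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .landscape import HabitatRaster, StudyDomain
from .movement import Trajectories

__all__ = [
    "Transect",
    "build_triangle",
    "generate_transect_network",
    "sample_survey_year",
    "count_crossings",
    "segment_crossings",
    "perimeter_lengths_by_class",
    "effective_effort",
    "survey_offset",
    "build_count_table",
    "FMP_GEOMETRY",
]

#: Ideal-gas geometry constant of the random encounter law, E[X] = (2/pi) a L M D.
FMP_GEOMETRY = 2.0 / np.pi


@dataclass(frozen=True)
class Transect:
    """One triangular survey route."""

    id: int
    center: tuple[float, float]
    rotation: float
    side: float = 4.0
    counting_day: int | None = None   # 1..60, assigned per survey year
    accumulation_days: float = 1.0    # D_it

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("side must be positive")

    @property
    def perimeter(self) -> float:
        return 3.0 * self.side

    @property
    def vertices(self) -> np.ndarray:
        """(3, 2) vertex coordinates; one vertex at angle ``rotation``."""
        R = self.side / np.sqrt(3.0)  # circumradius
        ang = self.rotation + np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        return np.column_stack([self.center[0] + R * np.cos(ang),
                                self.center[1] + R * np.sin(ang)])

    @property
    def edges(self) -> np.ndarray:
        """(3, 2, 2) array of edge endpoint pairs."""
        v = self.vertices
        return np.stack([v, np.roll(v, -1, axis=0)], axis=1)


def build_triangle(center, rotation: float, side: float = 4.0,
                   id: int = 0) -> Transect:
    """Equilateral triangle with centroid ``center`` and given rotation."""
    return Transect(id=id, center=(float(center[0]), float(center[1])),
                    rotation=float(rotation), side=float(side))


def _perimeter_points(transect: Transect, sample_step: float) -> np.ndarray:
    """Midpoint sample of the perimeter at ``sample_step`` km intervals."""
    edges = transect.edges
    m = max(int(np.ceil(transect.side / sample_step)), 1)
    frac = (np.arange(m) + 0.5) / m
    pts = edges[:, 0, None, :] + frac[None, :, None] * (
        edges[:, 1, None, :] - edges[:, 0, None, :])
    return pts.reshape(-1, 2)


def generate_transect_network(n: int, domain: StudyDomain,
                              raster: HabitatRaster,
                              rng: np.random.Generator,
                              min_reference_fraction: float = 0.0,
                              side: float = 4.0, sample_step: float = 0.025,
                              max_tries: int = 500) -> list[Transect]:
    """Place ``n`` random triangles, optionally constrained to the reference habitat.

    With ``min_reference_fraction > 0``, candidate placements are rejected
    until at least that fraction of the perimeter lies on the reference
    class inside the domain (the heterogeneous-landscape survey rule, 0.9).
    """
    transects: list[Transect] = []
    per_pt = None
    for _ in range(max_tries):
        need = n - len(transects)
        if need == 0:
            break
        centers = domain.sample_points(need, rng)
        rotations = rng.uniform(0, 2 * np.pi, size=need)
        for c, rot in zip(centers, rotations):
            tr = build_triangle(c, rot, side=side, id=len(transects))
            if min_reference_fraction > 0:
                pts = _perimeter_points(tr, sample_step)
                inside = domain.contains(pts[:, 0], pts[:, 1])
                codes = raster.habitat_at_or_zero(pts[:, 0], pts[:, 1])
                ok = inside & (codes == raster.reference_class)
                if ok.mean() < min_reference_fraction:
                    continue
            transects.append(tr)
    if len(transects) < n:
        raise RuntimeError("transect rejection cap exceeded: landscape has "
                           "too little reference habitat")
    return transects


def sample_survey_year(network: list[Transect], n_surveyed: int,
                       rng: np.random.Generator, season_days: int = 60,
                       redraw_rotation: bool = True) -> list[Transect]:
    """Pick the transects surveyed in one year.

    A uniform subset without replacement; each gets a uniform counting day
    in ``1..season_days`` and (by default) a freshly randomized rotation.
    Rotation redraw is switched off for networks whose placement was
    constrained to the reference habitat.
    """
    if n_surveyed > len(network):
        raise ValueError("cannot survey more transects than the network has")
    idx = rng.choice(len(network), size=n_surveyed, replace=False)
    days = rng.integers(1, season_days + 1, size=n_surveyed)
    out = []
    for i, d in zip(idx, days):
        tr = network[i]
        rot = rng.uniform(0, 2 * np.pi) if redraw_rotation else tr.rotation
        out.append(replace(tr, rotation=rot, counting_day=int(d)))
    return out


# --------------------------------------------------------------------------
# Crossing geometry
# --------------------------------------------------------------------------

def segment_crossings(segs: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Boolean (n_segs, n_edges) matrix of segment-segment intersections.

    Proper crossings, endpoint touches and grazing tangencies each count
    once; collinear overlap counts once (fixed convention for measure-zero
    configurations).
    """
    p1 = segs[:, None, 0]
    p2 = segs[:, None, 1]
    q1 = edges[None, :, 0]
    q2 = edges[None, :, 1]

    def cross(o, a, b):
        return ((a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1])
                - (a[..., 1] - o[..., 1]) * (b[..., 0] - o[..., 0]))

    d1 = cross(q1, q2, p1)
    d2 = cross(q1, q2, p2)
    d3 = cross(p1, p2, q1)
    d4 = cross(p1, p2, q2)
    straddle = (d1 * d2 <= 0) & (d3 * d4 <= 0)
    collinear = (d1 == 0) & (d2 == 0) & (d3 == 0) & (d4 == 0)
    # collinear: count once when the 1-D projections overlap
    lo_p = np.minimum(p1, p2)
    hi_p = np.maximum(p1, p2)
    lo_q = np.minimum(q1, q2)
    hi_q = np.maximum(q1, q2)
    overlap = np.all((lo_p <= hi_q) & (lo_q <= hi_p), axis=-1)
    return np.where(collinear, overlap, straddle)


def count_crossings(traj: Trajectories, transect: Transect,
                    steps_per_day: int = 6) -> int:
    """Track crossings X_it accumulated during the transect's counting day.

    The 24-h accumulation window is the ``steps_per_day`` movement steps of
    the counting day; every segment-edge intersection contributes the
    crossing agent's group size.
    """
    if transect.counting_day is None:
        raise ValueError("transect has no counting day assigned")
    segs = traj.day_segments(transect.counting_day, steps_per_day)
    n_agents, spd = segs.shape[:2]
    hits = segment_crossings(segs.reshape(-1, 2, 2), transect.edges)
    per_agent = hits.reshape(n_agents, spd * 3).sum(axis=1)
    return int(np.sum(per_agent * traj.group_sizes))


# --------------------------------------------------------------------------
# Effort
# --------------------------------------------------------------------------

def perimeter_lengths_by_class(transect: Transect, raster: HabitatRaster,
                               domain: StudyDomain,
                               sample_step: float = 0.025) -> np.ndarray:
    """In-domain perimeter length (km) on each habitat class.

    The perimeter is sampled at ``sample_step`` intervals (the land-cover
    resolution scale); out-of-domain or out-of-raster stretches contribute
    nothing.  Returns an (H,) array summing to the in-domain perimeter.
    """
    pts = _perimeter_points(transect, sample_step)
    seg_len = transect.perimeter / len(pts)
    inside = domain.contains(pts[:, 0], pts[:, 1])
    codes = raster.habitat_at_or_zero(pts[:, 0], pts[:, 1])
    codes = np.where(inside, codes, 0)
    counts = np.bincount(codes, minlength=raster.n_classes + 1)[1:]
    return counts * seg_len


def effective_effort(transect: Transect, raster: HabitatRaster,
                     weights: dict, domain: StudyDomain,
                     sample_step: float = 0.025) -> float:
    """Habitat-weighted effective transect length M_it (km).

    ``weights`` maps class label -> weight h (reference class 1); a class
    present in the raster but missing from the map raises KeyError.
    """
    lengths = perimeter_lengths_by_class(transect, raster, domain, sample_step)
    h = np.array([float(weights[lab]) for lab in raster.class_labels])
    return float(lengths @ h)


def survey_offset(m_km: float, el_km_per_day: float,
                  accumulation_days: float = 1.0) -> float:
    """Offset e_it = (2/pi) * E[L] * M_it * D_it of the encounter law."""
    return FMP_GEOMETRY * el_km_per_day * m_km * accumulation_days


def build_count_table(traj: Trajectories, surveyed: list[Transect],
                      raster: HabitatRaster, weights: dict,
                      domain: StudyDomain, el_km_per_day: float,
                      sample_step: float = 0.025,
                      steps_per_day: int = 6) -> pd.DataFrame:
    """Counts and effort for one survey year.

    Zero-effort records (transects fully outside the domain or on zero-weight
    habitat) are excluded, mirroring the survey's effort correction.
    """
    rows = []
    for tr in surveyed:
        m = effective_effort(tr, raster, weights, domain, sample_step)
        if m <= 0:
            continue
        x = count_crossings(traj, tr, steps_per_day)
        rows.append({"transect_id": tr.id, "count": x,
                     "counting_day": tr.counting_day,
                     "x_km": tr.center[0], "y_km": tr.center[1],
                     "M_km_weighted": m, "D_days": tr.accumulation_days,
                     "offset": survey_offset(m, el_km_per_day,
                                             tr.accumulation_days)})
    return pd.DataFrame(rows, columns=["transect_id", "count", "counting_day",
                                       "x_km", "y_km", "M_km_weighted",
                                       "D_days", "offset"])
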