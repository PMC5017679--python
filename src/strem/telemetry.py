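"""GPS collaring, daily movement distance, and step-selection habitat weights.

A burst is one collared individual's 4-hourly fix sequence over one survey
season.  The expected daily movement distance E[L] is the average of the
24-hour path sums over burst-days.  Habitat preference is estimated with a
step-selection null model: each realized step is compared with 30 null steps
resampled from the burst's own empirical turning-angle and step-length
distributions, yielding used (p) versus available (q) habitat fractions.
Preferences pool across bursts as a ratio of sums, w_i = sum_k p_ik /
sum_k q_ik, and convert to weights relative to the reference (forest) class,
h_i = w_i / w_ref.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import HabitatRaster, StudyDomain
from .movement import Trajectories

__all__ = [
    "GpsBurst",
    "HabitatWeightMap",
    "collar_individuals",
    "estimate_daily_distance",
    "generate_null_steps",
    "burst_usage",
    "pooled_preferences",
    "relative_weights",
    "estimate_habitat_weights",
    "bootstrap_weight_intervals",
]


@dataclass
class GpsBurst:
    """Fix sequence of one collared individual over one season."""

    individual_id: int
    fixes: np.ndarray       # (m, 2) km, time-ordered at step_hours interval
    step_hours: float = 4.0

    def __post_init__(self) -> None:
        self.fixes = np.asarray(self.fixes, dtype=float)
        if self.fixes.ndim != 2 or len(self.fixes) < 2:
            raise ValueError("a burst needs at least two fixes")

    @property
    def n_steps(self) -> int:
        return len(self.fixes) - 1

    @property
    def step_lengths(self) -> np.ndarray:
        d = np.diff(self.fixes, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def headings(self) -> np.ndarray:
        d = np.diff(self.fixes, axis=0)
        return np.arctan2(d[:, 1], d[:, 0])

    @property
    def turning_angles(self) -> np.ndarray:
        """Turning angles of steps 2..J (undefined for the first step)."""
        h = self.headings
        return np.angle(np.exp(1j * np.diff(h)))

    @classmethod
    def from_trajectory(cls, traj: Trajectories, agent: int) -> "GpsBurst":
        return cls(individual_id=agent, fixes=traj.fixes[agent],
                   step_hours=traj.step_hours)

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(len(self.fixes)) * self.step_hours / 24.0
        return pd.DataFrame({"individual_id": self.individual_id,
                             "t_days": t, "x_km": self.fixes[:, 0],
                             "y_km": self.fixes[:, 1]})


@dataclass
class HabitatWeightMap:
    """Pooled step-selection preferences and relative habitat weights."""

    class_labels: tuple[str, ...]
    p: np.ndarray           # pooled usage sums per class
    q: np.ndarray           # pooled null-availability sums per class
    w: np.ndarray           # preference ratio, NaN where pooled q == 0
    h: np.ndarray           # weight relative to the reference class
    reference_class: int    # 1-based code

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.w)

    def as_dict(self) -> dict:
        return {lab: float(self.h[i]) for i, lab in enumerate(self.class_labels)}


def collar_individuals(n_agents: int, n: int, rng: np.random.Generator
                       ) -> np.ndarray:
    """Uniformly sample (without replacement) the agents to collar this year."""
    if n_agents < 1:
        raise ValueError("population must be nonempty")
    return rng.choice(n_agents, size=min(n, n_agents), replace=False)


def estimate_daily_distance(bursts: list[GpsBurst],
                            steps_per_day: int = 6) -> float:
    """E[L]: mean 24-h path distance over full burst-days and individuals."""
    if not bursts:
        raise ValueError("no bursts supplied")
    daily = []
    for b in bursts:
        lens = b.step_lengths
        n_days = len(lens) // steps_per_day
        if n_days < 1:
            continue
        daily.append(lens[:n_days * steps_per_day]
                     .reshape(n_days, steps_per_day).sum(axis=1))
    if not daily:
        raise ValueError("no complete burst-days available")
    return float(np.concatenate(daily).mean())


def generate_null_steps(burst: GpsBurst, domain: StudyDomain,
                        rng: np.random.Generator, n_null: int = 30,
                        max_redraws: int = 10_000) -> np.ndarray:
    """Null endpoints for every selection step of the burst.

    For step j (j >= 2; the first step has no turning angle and is
    excluded), ``n_null`` endpoints start at the realized start of step j
    with heading ``heading_{j-1} + turn*`` and length ``len*``, where turn*
    and len* are drawn independently from the burst's empirical turning-angle
    and step-length distributions.  Endpoints outside the domain are redrawn,
    mirroring the movement boundary rule.  Returns shape
    ``(n_steps - 1, n_null, 2)``.
    """
    turns = burst.turning_angles
    lens = burst.step_lengths
    if len(turns) < 1:
        raise ValueError("burst needs at least 2 steps for null generation")
    if np.all(lens == 0):
        raise ValueError("degenerate burst: all fixes identical")
    starts = burst.fixes[1:-1]          # start point of steps 2..J
    prev_head = burst.headings[:-1]     # heading of the preceding step
    J = len(starts)
    out = np.empty((J, n_null, 2))
    todo = np.ones((J, n_null), dtype=bool)
    for _ in range(max_redraws):
        m = int(todo.sum())
        if m == 0:
            return out
        t = turns[rng.integers(0, len(turns), size=m)]
        l = lens[rng.integers(0, len(lens), size=m)]
        rows = np.nonzero(todo)[0]
        head = prev_head[rows] + t
        pts = starts[rows] + np.column_stack([l * np.cos(head),
                                              l * np.sin(head)])
        ok = domain.contains(pts[:, 0], pts[:, 1])
        out[todo] = pts
        todo[tuple(np.nonzero(todo))] = ~ok
    raise RuntimeError("null-step redraw cap exceeded")


def burst_usage(burst: GpsBurst, raster: HabitatRaster,
                null_steps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class used (p_ik) and available (q_ik) fractions for one burst.

    ``p`` averages the indicator of the realized endpoints' classes over the
    selection steps; ``q`` averages the per-step fraction of null endpoints
    in each class.  Both sum to one over classes.
    """
    H = raster.n_classes
    ends = burst.fixes[2:]              # endpoints of steps 2..J
    J = len(ends)
    if null_steps.shape[0] != J:
        raise ValueError("null steps do not match the burst's selection steps")
    used = raster.habitat_at_or_zero(ends[:, 0], ends[:, 1])
    p = np.bincount(used[used > 0], minlength=H + 1)[1:] / J
    flat = null_steps.reshape(-1, 2)
    avail = raster.habitat_at_or_zero(flat[:, 0], flat[:, 1])
    n_null = null_steps.shape[1]
    q = np.bincount(avail[avail > 0], minlength=H + 1)[1:] / (J * n_null)
    return p, q


def pooled_preferences(usages: list[tuple[np.ndarray, np.ndarray]]
                       ) -> np.ndarray:
    """Preference w_i as the ratio of pooled sums (not a mean of ratios).

    Classes never available in any burst (pooled q == 0) come out NaN,
    flagging an undefined preference rather than zero.
    """
    P = np.sum([p for p, _ in usages], axis=0)
    Q = np.sum([q for _, q in usages], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(Q > 0, P / np.where(Q > 0, Q, 1.0), np.nan)
    return w


def relative_weights(w: np.ndarray, reference_class: int,
                     class_labels: tuple[str, ...],
                     p=None, q=None) -> HabitatWeightMap:
    """Normalize preferences to the reference class: h_i = w_i / w_ref."""
    w = np.asarray(w, dtype=float)
    w_ref = w[reference_class - 1]
    if not np.isfinite(w_ref) or w_ref <= 0:
        raise ValueError("reference-class preference is zero or undefined")
    h = w / w_ref
    h[reference_class - 1] = 1.0
    return HabitatWeightMap(class_labels=tuple(class_labels),
                            p=np.asarray(p) if p is not None else np.full_like(w, np.nan),
                            q=np.asarray(q) if q is not None else np.full_like(w, np.nan),
                            w=w, h=h, reference_class=reference_class)


def estimate_habitat_weights(bursts: list[GpsBurst], raster: HabitatRaster,
                             domain: StudyDomain, rng: np.random.Generator,
                             n_null: int = 30) -> HabitatWeightMap:
    """Full step-selection pipeline from bursts to relative habitat weights."""
    usages = []
    for b in bursts:
        nulls = generate_null_steps(b, domain, rng, n_null=n_null)
        usages.append(burst_usage(b, raster, nulls))
    w = pooled_preferences(usages)
    P = np.sum([p for p, _ in usages], axis=0)
    Q = np.sum([q for _, q in usages], axis=0)
    return relative_weights(w, raster.reference_class, raster.class_labels,
                            p=P, q=Q)


def bootstrap_weight_intervals(usages: list[tuple[np.ndarray, np.ndarray]],
                               reference_class: int,
                               rng: np.random.Generator,
                               n_boot: int = 1000, level: float = 0.95
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap intervals of h, resampling bursts with replacement."""
    K = len(usages)
    P = np.stack([p for p, _ in usages])
    Q = np.stack([q for _, q in usages])
    hs = np.full((n_boot, P.shape[1]), np.nan)
    for i in range(n_boot):
        idx = rng.integers(0, K, size=K)
        Pb = P[idx].sum(axis=0)
        Qb = Q[idx].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(Qb > 0, Pb / np.where(Qb > 0, Qb, 1.0), np.nan)
        ref = w[reference_class - 1]
        if np.isfinite(ref) and ref > 0:
            hs[i] = w / ref
    alpha = (1.0 - level) / 2.0
    lo = np.nanquantile(hs, alpha, axis=0)
    hi = np.nanquantile(hs, 1.0 - alpha, axis=0)
    return lo, hi
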