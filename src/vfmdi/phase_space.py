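"""Delay embedding, maximal Lyapunov exponent, and quasi-period extraction.

A scalar signal :math:`p_n` is lifted into an m-dimensional state space with
lagged copies, ``P = [p_n, p_{n-tau}, ..., p_{n-(m-1)tau}]``.  On the
reconstructed trajectory we estimate the maximal Lyapunov exponent with the
Rosenstein nearest-neighbour divergence method (robust for short, noisy
series), and extract *quasi-periods* — the times between successive returns
of the trajectory into a small neighbourhood of a reference state, with a
Theiler window excluding trivially correlated neighbours.  Positive Lyapunov
exponents on VF segments are the rationale for this nonlinear
characterization; the quasi-period sample is the raw input to the QPD-PD
feature construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import BoundaryError, DegenerateInputError, ParameterError
from .types import SignalSegment

__all__ = [
    "EmbeddingParams",
    "Trajectory",
    "QuasiPeriodSample",
    "embed",
    "max_lyapunov",
    "quasi_periods",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters: dimension ``m`` and delay ``tau`` (samples).

    Defaults (m=4, tau=8) are the values found adequate for 9-s VF segments;
    tau must be large enough that successive coordinates are informative but
    small enough that the state retains memory.
    """

    m: int = 4
    tau: int = 8

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ParameterError("require m >= 1 and tau >= 1")


@dataclass(frozen=True)
class Trajectory:
    """Reconstructed phase-space trajectory (points x m array)."""

    points: np.ndarray
    m: int
    tau: int
    source_rate: float

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def diameter(self) -> float:
        """Bounding-box diagonal of the attractor (scale-aware, O(N))."""
        rng = self.points.max(axis=0) - self.points.min(axis=0)
        return float(np.sqrt(np.sum(rng**2)))


@dataclass
class QuasiPeriodSample:
    """Pooled recurrence times (seconds) over all reference points."""

    durations: np.ndarray
    empty_warning: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)


def embed(seg: SignalSegment, params: EmbeddingParams = EmbeddingParams()) -> Trajectory:
    """Delay-embed a segment; point k is (p_{k+(m-1)tau}, ..., p_{k+tau}, p_k)."""
    m, tau = params.m, params.tau
    n = seg.n
    count = n - (m - 1) * tau
    if count <= 0:
        raise BoundaryError(
            f"segment of {n} samples too short for m={m}, tau={tau}"
        )
    cols = [seg.samples[(m - 1 - j) * tau : (m - 1 - j) * tau + count] for j in range(m)]
    return Trajectory(np.column_stack(cols), m, tau, seg.sampling_rate)


def max_lyapunov(
    traj: Trajectory,
    min_separation: int | None = None,
    fit_range: int | None = None,
    fit_start: int = 0,
) -> float:
    """Maximal Lyapunov exponent (1/s), Rosenstein nearest-neighbour method.

    For each trajectory point the nearest neighbour at temporal separation
    >= ``min_separation`` (Theiler exclusion, default ``m * tau``) is found;
    the mean log distance between the two evolving trajectories is tracked
    for ``fit_range`` steps (default one mean-period heuristic, 1/10 of the
    trajectory capped at 80 samples) and the exponent is the least-squares
    slope of that curve versus time over steps ``[fit_start, fit_range]``.
    ``fit_start > 0`` skips the initial neighbour-relaxation transient when
    a clean scaling region is known (clean deterministic flows).
    """
    pts = traj.points
    n = traj.n_points
    if n < 50:
        raise ParameterError("need >= 50 trajectory points")
    if float(np.max(pts.max(axis=0) - pts.min(axis=0))) == 0.0:
        raise DegenerateInputError("all trajectory points identical")
    if min_separation is None:
        min_separation = traj.m * traj.tau
    if fit_range is None:
        fit_range = min(80, max(10, n // 10))

    tree = cKDTree(pts)
    # enough candidates to clear the Theiler window
    k = min(n, 2 * min_separation + 2)
    dist, idx = tree.query(pts, k=k)
    sep = np.abs(idx - np.arange(n)[:, None])
    valid = sep > min_separation
    # first valid neighbour per point
    first = np.argmax(valid, axis=1)
    has = valid[np.arange(n), first]
    nn = idx[np.arange(n), first]
    ref = np.flatnonzero(has & (np.arange(n) + fit_range < n) & (nn + fit_range < n))
    if ref.size < 10:
        raise DegenerateInputError("too few neighbour pairs for divergence curve")
    nn = nn[ref]

    if not 0 <= fit_start < fit_range:
        raise ParameterError("require 0 <= fit_start < fit_range")
    eps = 1e-12 * max(traj.diameter(), 1.0)
    steps = np.arange(fit_start, fit_range + 1)
    mean_log = np.empty(steps.size)
    for i, s in enumerate(steps):
        d = np.linalg.norm(pts[ref + s] - pts[nn + s], axis=1)
        mean_log[i] = float(np.mean(np.log(d + eps)))
    t = steps / traj.source_rate
    slope = np.polyfit(t, mean_log, 1)[0]
    return float(slope)


def quasi_periods(
    traj: Trajectory,
    eps_fraction: float = 0.15,
    theiler: int | None = None,
    ref_stride: int = 5,
) -> QuasiPeriodSample:
    """Recurrence times of the trajectory into eps-balls around references.

    For each reference point (subsampled with a stride for O(N) cost) the
    times between successive *entries* into the ball of radius
    ``eps_fraction * diameter`` are recorded, ignoring sojourns shorter than
    the Theiler window; durations are pooled over all reference points.
    """
    if not 0.0 < eps_fraction < 1.0:
        raise ParameterError("eps_fraction must be in (0, 1)")
    if theiler is None:
        theiler = traj.m * traj.tau
    if theiler < 1:
        raise ParameterError("theiler must be >= 1")
    diam = traj.diameter()
    if diam == 0.0:
        raise DegenerateInputError("zero attractor diameter (constant signal)")
    pts = traj.points
    n = traj.n_points
    stride = max(1, min(int(ref_stride), n))
    eps = eps_fraction * diam
    tree = cKDTree(pts)
    refs = np.arange(0, n, stride)
    neigh = tree.query_ball_point(pts[refs], eps)
    durations: list[float] = []
    for r, inside in zip(refs, neigh):
        inside = np.sort(np.asarray(inside, dtype=int))
        if inside.size < 2:
            continue
        # collapse consecutive-index runs to single entries, honouring the
        # Theiler window as the minimum gap that counts as leaving the ball
        gaps = np.diff(inside)
        entry = inside[np.concatenate(([True], gaps > theiler))]
        # drop entries whose sojourn may be truncated by the array edges
        entry = entry[(entry >= theiler) & (entry <= n - 1 - theiler)]
        if entry.size < 2:
            continue
        durations.extend(np.diff(entry) / traj.source_rate)
    arr = np.asarray(durations, dtype=float)
    return QuasiPeriodSample(arr, empty_warning=arr.size == 0,
                             meta={"eps": eps, "theiler": theiler})
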