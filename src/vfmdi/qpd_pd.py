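"""Quasi-Period Density / Prototype-Distance (QPD-PD) features.

The quasi-period sample of a segment (recurrence times of its phase-space
trajectory) is binned into a normalized histogram, then smoothed into a
probability density by convolution with a causal exponential kernel
``e^{-t/4}`` — mass at a quasi-period t0 spreads forward with decay constant
4 (seconds by default), which quantifies how concentrated the quasi-periods
are.  Features are distances (``KD``) between a segment's smoothed density
and the densities of a small *prototype set* (C per class, default 4): the
distance formula is pluggable and defaults to the Jeffreys (symmetrized
Kullback–Leibler) divergence on floor-regularized common-grid PDFs.

The scalar criterion *sep* scores how well a parameterization separates the
two prototype classes:

    sep = sum_i [ mean(KD_i^B) - mean(KD_i^W) ]
                 / max( Var_i^B, Var_i^W )

with the between/within variances computed with divisors C^B and C^W
(C^W = own-class count minus one).  As written this quantity is *not*
invariant to a common rescaling of all distances (sep(s*KD) = sep(KD)/s);
it is implemented exactly in that form.  *sep* maximization over a
parameter grid selects the QPD parameterization used for feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigError,
    DegenerateVarianceError,
    EmptyDensityError,
    GridError,
    ParameterError,
    SelectionError,
)
from .phase_space import EmbeddingParams, QuasiPeriodSample, embed, quasi_periods
from .types import Outcome, SignalSegment

__all__ = [
    "QpdParams",
    "QuasiPeriodDensity",
    "PrototypeSet",
    "SepValue",
    "qpd_histogram",
    "smooth_pdf",
    "kd_distance",
    "sep",
    "density_for_segment",
    "select_prototypes",
    "select_parameters",
    "prototype_features",
]

#: variance floor below which a sep denominator is considered degenerate
VAR_FLOOR = 1e-12
#: probability floor applied before log-ratio distances; small enough not to
#: clip genuine tail contributions, nonzero so log ratios stay finite
PDF_FLOOR = 1e-30


@dataclass(frozen=True)
class QpdParams:
    """One QPD parameterization (the grid axes of *sep* selection)."""

    bin_width: float = 0.05       # s, histogram bin width
    t_max: float = 1.5            # s, histogram range; longer periods pool in last bin
    eps_fraction: float = 0.15    # recurrence ball radius / attractor diameter
    theiler: Optional[int] = None  # samples; None -> m * tau
    kernel_scale: float = 4.0     # decay constant of the exponential kernel
    grid_step: float = 0.01       # s, PDF evaluation grid step
    tail_extent: float = 2.0      # s, PDF grid extension past t_max

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.t_max <= 0 or self.grid_step <= 0:
            raise ParameterError("bin_width, t_max and grid_step must be > 0")


@dataclass
class QuasiPeriodDensity:
    """Normalized quasi-period histogram and its smoothed PDF."""

    bin_edges: np.ndarray          # s, len = n_bins + 1
    mass: np.ndarray               # per-bin probability, sums to 1
    pdf_grid: Optional[np.ndarray] = None   # density on `grid`, integrates to 1
    grid: Optional[np.ndarray] = None       # s, uniform
    params: Optional[QpdParams] = None
    segment_id: str = ""

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PrototypeSet:
    """2C class-labelled densities sharing one parameterization."""

    entries: List[Tuple[Outcome, QuasiPeriodDensity, str]]
    params: QpdParams

    def __post_init__(self) -> None:
        labels = {lab for lab, _, _ in self.entries}
        if labels != {Outcome.SUCCESSFUL, Outcome.UNSUCCESSFUL}:
            raise ConfigError("prototype set must contain both classes")

    def ordered(self) -> List[Tuple[Outcome, QuasiPeriodDensity, str]]:
        """Deterministic order: class (successful first) then id."""
        return sorted(self.entries, key=lambda e: (-int(e[0]), e[2]))


@dataclass
class SepValue:
    value: float
    per_signal_terms: np.ndarray


def qpd_histogram(
    sample: QuasiPeriodSample, bin_width: float = 0.05, t_max: float = 1.5
) -> QuasiPeriodDensity:
    """Normalized histogram of quasi-periods on [0, t_max].

    Durations beyond ``t_max`` accumulate in the last bin, so mass is
    conserved for long-period outliers.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    d = np.asarray(sample.durations, dtype=float)
    if d.size == 0:
        raise EmptyDensityError("no quasi-periods recorded for this segment")
    n_bins = max(1, int(np.ceil(t_max / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    clipped = np.minimum(d, edges[-1] - 0.5 * bin_width)
    counts, _ = np.histogram(clipped, bins=edges)
    mass = counts / counts.sum()
    return QuasiPeriodDensity(edges, mass)


def smooth_pdf(density: QuasiPeriodDensity, params: QpdParams = QpdParams()) -> QuasiPeriodDensity:
    """Smooth the histogram into a PDF with the causal exponential kernel.

    ``pdf(t) ∝ Σ_b mass_b · exp(-(t - c_b)/scale) · 1[t >= c_b]`` on a
    uniform grid covering the histogram plus a tail extension; the result is
    renormalized to integrate to 1 over that grid.
    """
    if not np.isclose(density.mass.sum(), 1.0, atol=1e-9):
        raise ParameterError("density must be normalized before smoothing")
    step = params.grid_step
    t_end = density.bin_edges[-1] + params.tail_extent
    grid = np.arange(0.0, t_end + 0.5 * step, step)
    centers = density.centers
    delta = grid[:, None] - centers[None, :]
    kern = np.where(delta >= 0.0, np.exp(-delta / params.kernel_scale), 0.0)
    pdf = kern @ density.mass
    norm = np.trapezoid(pdf, grid)
    if norm <= 0:
        raise EmptyDensityError("smoothed PDF has zero mass")
    out = replace(density)
    out.pdf_grid = pdf / norm
    out.grid = grid
    out.params = params
    return out


def _grid_probs(d: QuasiPeriodDensity) -> np.ndarray:
    if d.pdf_grid is None or d.grid is None:
        raise GridError("density has no smoothed PDF; call smooth_pdf first")
    p = d.pdf_grid * np.gradient(d.grid)
    p = np.maximum(p, PDF_FLOOR)
    return p / p.sum()


def kd_distance(a: QuasiPeriodDensity, b: QuasiPeriodDensity) -> float:
    """Jeffreys (symmetrized KL) divergence between two smoothed densities."""
    if a.grid is None or b.grid is None:
        raise GridError("both densities need smoothed PDFs")
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise GridError("densities are not on a common grid")
    p, q = _grid_probs(a), _grid_probs(b)
    return float(np.sum((p - q) * (np.log(p) - np.log(q))))


def sep(kd_matrix: np.ndarray, labels: Sequence[int]) -> SepValue:
    """Class-separation criterion over an L x L prototype distance matrix.

    For each prototype i the between-class mean minus within-class mean
    (self excluded) is divided by the larger of the two variance terms
    (divisors C^B and C^W respectively); terms are summed over prototypes.
    """
    kd = np.asarray(kd_matrix, dtype=float)
    labels = np.asarray(labels)
    L = kd.shape[0]
    if kd.shape != (L, L):
        raise ParameterError("kd_matrix must be square (full prototype set)")
    terms = np.empty(L)
    for i in range(L):
        own = (labels == labels[i]) & (np.arange(L) != i)
        opp = labels != labels[i]
        if own.sum() == 0 or opp.sum() == 0:
            raise ParameterError("each prototype needs within- and between-class peers")
        kd_w, kd_b = kd[i, own], kd[i, opp]
        mean_w, mean_b = kd_w.mean(), kd_b.mean()
        var_w = np.sum((kd_w - mean_w) ** 2) / kd_w.size
        var_b = np.sum((kd_b - mean_b) ** 2) / kd_b.size
        denom = max(var_b, var_w)
        if denom < VAR_FLOOR:
            raise DegenerateVarianceError(
                f"prototype {i}: both variance terms below {VAR_FLOOR}"
            )
        terms[i] = (mean_b - mean_w) / denom
    return SepValue(float(terms.sum()), terms)


# --------------------------------------------------------------------------
# Pipeline glue: segment -> density, prototype selection, parameter search
# --------------------------------------------------------------------------

def density_for_segment(
    seg: SignalSegment,
    params: QpdParams = QpdParams(),
    embedding: EmbeddingParams = EmbeddingParams(),
    ref_stride: int = 5,
) -> QuasiPeriodDensity:
    """Full chain: embed -> quasi-periods -> histogram -> smoothed PDF."""
    traj = embed(seg, embedding)
    theiler = params.theiler if params.theiler is not None else embedding.m * embedding.tau
    sample = quasi_periods(traj, params.eps_fraction, theiler, ref_stride)
    dens = qpd_histogram(sample, params.bin_width, params.t_max)
    dens = smooth_pdf(dens, params)
    dens.segment_id = seg.segment_id
    return dens


def _pairwise_kd(densities: Sequence[QuasiPeriodDensity]) -> np.ndarray:
    """Vectorized pairwise Jeffreys divergence matrix."""
    P = np.stack([_grid_probs(d) for d in densities])
    logP = np.log(P)
    # J(p,q) = sum((p-q)(log p - log q)) expanded into dot products
    a = np.einsum("ij,ij->i", P, logP)
    cross1 = P @ logP.T
    return a[:, None] + a[None, :] - cross1 - cross1.T


def select_prototypes(
    densities: Dict[str, QuasiPeriodDensity],
    outcomes: Dict[str, Outcome],
    params: QpdParams,
    n_per_class: int = 4,
    explicit_ids: Optional[Sequence[str]] = None,
) -> PrototypeSet:
    """Build the prototype set: explicit ids, or per-class KD medoids.

    Medoids are the ``n_per_class`` segments with the smallest summed
    within-class distance, computed only from the densities supplied
    (training fold).
    """
    if explicit_ids is not None:
        entries = [(outcomes[i], densities[i], i) for i in explicit_ids]
        return PrototypeSet(entries, params)
    entries = []
    for cls in (Outcome.SUCCESSFUL, Outcome.UNSUCCESSFUL):
        ids = sorted(i for i, o in outcomes.items() if o == cls and i in densities)
        if len(ids) < n_per_class:
            raise ConfigError(
                f"class {cls.name} has {len(ids)} candidates < {n_per_class}"
            )
        mat = _pairwise_kd([densities[i] for i in ids])
        order = np.argsort(mat.sum(axis=1), kind="stable")[:n_per_class]
        entries.extend((cls, densities[ids[k]], ids[k]) for k in sorted(order))
    return PrototypeSet(entries, params)


def sep_for_prototypes(ps: PrototypeSet) -> SepValue:
    ordered = ps.ordered()
    kd = _pairwise_kd([d for _, d, _ in ordered])
    labels = [int(lab) for lab, _, _ in ordered]
    return sep(kd, labels)


def select_parameters(
    train_segments: Dict[str, SignalSegment],
    outcomes: Dict[str, Outcome],
    param_grid: Sequence[QpdParams],
    prototype_ids: Optional[Sequence[str]] = None,
    embedding: EmbeddingParams = EmbeddingParams(),
    n_per_class: int = 4,
    ref_stride: int = 5,
) -> Tuple[QpdParams, PrototypeSet, pd.DataFrame]:
    """Maximize *sep* over a QPD parameter grid (training fold only).

    Returns the argmax parameterization (first in grid order on ties), the
    prototype set built with it, and a trace with one row per grid point
    carrying *sep* alongside the comparison heuristics (mean ANOVA F over
    the KD features, accumulated ANOVA and Kruskal–Wallis false-positive
    probabilities) for diagnostic plots.  Grid points whose sep is
    degenerate are skipped and logged in the trace.
    """
    if len(param_grid) == 0:
        raise SelectionError("empty parameter grid")
    rows = []
    best: Tuple[float, int, QpdParams, PrototypeSet] | None = None
    for g, params in enumerate(param_grid):
        try:
            dens = {
                i: density_for_segment(seg, params, embedding, ref_stride)
                for i, seg in train_segments.items()
            }
            ps = select_prototypes(dens, outcomes, params, n_per_class, prototype_ids)
            s = sep_for_prototypes(ps)
        except (DegenerateVarianceError, EmptyDensityError) as exc:
            rows.append({"grid_index": g, "sep": np.nan, "mean_F": np.nan,
                         "anova_p_fp": np.nan, "kw_p_fp": np.nan,
                         "skipped": str(exc), **_params_row(params)})
            continue
        rows.append({"grid_index": g, "sep": s.value,
                     **_heuristics(dens, outcomes, ps),
                     "skipped": "", **_params_row(params)})
        if best is None or s.value > best[0]:
            best = (s.value, g, params, ps)
    trace = pd.DataFrame(rows)
    if best is None:
        raise SelectionError("sep degenerate at every grid point")
    return best[2], best[3], trace


def _heuristics(dens, outcomes, ps: PrototypeSet) -> dict:
    """ANOVA/KW heuristics of the KD feature set for one grid point."""
    from .feature_space import accumulate_fp, anova_per_feature, kw_per_feature

    rows = [prototype_features(dens[i], ps) for i in sorted(dens)]
    feats = pd.DataFrame(rows)
    feats["outcome"] = [int(outcomes[i]) for i in sorted(dens)]
    if feats["outcome"].nunique() < 2:
        return {"mean_F": np.nan, "anova_p_fp": np.nan, "kw_p_fp": np.nan}
    an = anova_per_feature(feats)
    kw = kw_per_feature(feats)
    return {
        "mean_F": float(an["F"].mean()),
        "anova_p_fp": float(accumulate_fp(an["p"])["p_fp"].iloc[-1]),
        "kw_p_fp": float(accumulate_fp(kw["p"])["p_fp"].iloc[-1]),
    }


def _params_row(p: QpdParams) -> dict:
    return {
        "bin_width": p.bin_width,
        "t_max": p.t_max,
        "eps_fraction": p.eps_fraction,
        "theiler": p.theiler if p.theiler is not None else -1,
    }


def prototype_features(
    seg_density: QuasiPeriodDensity, ps: PrototypeSet
) -> Dict[str, float]:
    """KD from a segment's density to every prototype (2C named features)."""
    if seg_density.params != ps.params:
        raise ConfigError("segment density parameterization differs from prototypes")
    feats = {}
    for k, (lab, dens, pid) in enumerate(ps.ordered()):
        name = f"kd_{'succ' if lab == Outcome.SUCCESSFUL else 'unsucc'}_{k % max(1, len(ps.entries) // 2)}"
        feats[name] = kd_distance(seg_density, dens)
    return feats
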