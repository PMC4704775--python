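"""Adaptive two-stage ECG filter: smoothing then baseline removal.

Stage 1 suppresses high-frequency noise with a Savitzky–Golay (SG) filter
(degree-11 polynomials over 25-sample frames by default), which preserves
sharp physiologic morphology that a plain low-pass would smear.  Stage 2
estimates the slow baseline (shifts, drifts, step artifacts) with a wide
cubic SG smoother (frames of up to 499 samples) and subtracts it from the
stage-1 output.

Baseline edge handling matters: fitting the raw oscillatory signal in
one-sided windows leaks large spurious edge baselines, so the baseline is
computed on interior (full-window) positions only and extended to the edges
by polynomial extrapolation of the already-smooth interior estimate.

The baseline smoother can be applied repeatedly ("successive smoothing",
with a max-abs inter-pass change tolerance and a pass cap), but each extra
pass widens the transition around step artifacts faster than it improves
oscillation suppression, so the default is a single pass; the iteration
controls stay configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._sg import _interior_kernel, sg_filter
from .exceptions import ParameterError
from .types import SignalSegment

__all__ = ["FilterConfig", "sg_smooth", "estimate_baseline", "detrend"]


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the two-stage filter.

    ``sg_order``/``sg_frame`` control the smoothing stage, ``base_*`` the
    baseline stage.  Frames must be odd and larger than the polynomial
    order; ``base_frame`` is clipped to the largest odd value not exceeding
    the segment length.  ``base_tol`` (mV) is the max-abs inter-pass change
    below which successive baseline smoothing stops.
    """

    sg_order: int = 11
    sg_frame: int = 25
    base_order: int = 3
    base_frame: int = 499
    base_passes_max: int = 1
    base_tol: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("sg_frame", "base_frame"):
            if getattr(self, name) % 2 == 0:
                raise ParameterError(f"{name} must be odd")
        if self.sg_order >= self.sg_frame or self.base_order >= self.base_frame:
            raise ParameterError("polynomial order must be < frame length")
        if not self.base_tol > 0:
            raise ParameterError("base_tol must be > 0")
        if self.base_passes_max < 1:
            raise ParameterError("base_passes_max must be >= 1")


def _check(order: int, frame: int, n: int) -> None:
    if frame % 2 == 0:
        raise ParameterError(f"frame must be odd, got {frame}")
    if not order < frame:
        raise ParameterError(f"order {order} must be < frame {frame}")
    if frame > n:
        raise ParameterError(f"frame {frame} exceeds segment length {n}")


def sg_smooth(seg: SignalSegment, order: int = 11, frame: int = 25) -> SignalSegment:
    """Savitzky–Golay smoothing; exact on polynomials of degree <= order.

    Boundary samples are fitted on truncated one-sided windows, so no
    implicit padding leaks into a 9-s segment.
    """
    _check(order, frame, seg.n)
    return seg.with_samples(sg_filter(seg.samples, frame, order))


def clip_frame(frame: int, n: int) -> int:
    """Largest odd frame <= min(frame, n)."""
    f = min(frame, n)
    return f if f % 2 == 1 else f - 1


def _baseline_pass(x: np.ndarray, frame: int, order: int) -> np.ndarray:
    """One wide-frame SG pass; edges extrapolated from the interior fit."""
    n = len(x)
    half = frame // 2
    kern = _interior_kernel(frame, order)
    interior = np.convolve(x, kern[::-1], mode="valid")   # positions half..n-half-1
    out = np.empty(n)
    out[half:n - half] = interior
    m = min(frame, interior.size)
    left = np.polynomial.Polynomial.fit(np.arange(half, half + m), interior[:m], order)
    out[:half] = left(np.arange(half))
    right = np.polynomial.Polynomial.fit(
        np.arange(n - half - m, n - half), interior[-m:], order)
    out[n - half:] = right(np.arange(n - half, n))
    return out


def estimate_baseline(
    seg: SignalSegment,
    order: int = 3,
    frame: int = 499,
    passes_max: int = 1,
    tol: float = 1e-3,
) -> SignalSegment:
    """Estimate the slow baseline by (optionally successive) SG smoothing.

    With ``passes_max > 1`` the smoother is reapplied until the maximum
    absolute change between passes drops below ``tol`` or the cap is hit;
    non-convergence is recorded in the result metadata
    (``baseline_converged``), not raised.
    """
    frame = clip_frame(frame, seg.n)
    _check(order, frame, seg.n)
    y = seg.samples
    converged = passes_max == 1
    passes = 0
    for passes in range(1, passes_max + 1):
        y_new = _baseline_pass(y, frame, order)
        if passes > 1 and float(np.max(np.abs(y_new - y))) < tol:
            y = y_new
            converged = True
            break
        y = y_new
    return seg.with_samples(y, baseline_converged=converged, baseline_passes=passes)


def detrend(seg: SignalSegment, config: FilterConfig = FilterConfig()) -> SignalSegment:
    """Full two-stage filter: smooth, then subtract the estimated baseline."""
    smooth = sg_smooth(seg, config.sg_order, config.sg_frame)
    base = estimate_baseline(
        smooth,
        config.base_order,
        config.base_frame,
        config.base_passes_max,
        config.base_tol,
    )
    out = smooth.with_samples(smooth.samples - base.samples)
    out.meta.update(base.meta)
    return out
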