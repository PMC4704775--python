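"""Shift-invariant complex wavelet subband features and time-domain descriptors.

Because pre-shock segments are cut by windowing, a decimated wavelet
transform would make the features depend strongly on where the window
happens to fall.  The decomposition here is a dual-branch analytic
stationary wavelet transform: an undecimated orthogonal DWT (norm-preserving
``pywt.swt``) is applied to the signal and, in a second branch, to its
Hilbert quadrature; the two branches combine into complex per-level
coefficients whose magnitudes are insensitive to small shifts of the input.
The transform is invertible from the real branch alone (near-perfect
reconstruction) and partitions energy across levels.

Per-level statistics (energy, mean magnitude, magnitude std, normalized
log-energy entropy) plus a small set of time-domain descriptors complete
the non-QPD part of the feature set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pywt
from scipy.signal import hilbert

from .exceptions import BoundaryError
from .types import SignalSegment

__all__ = ["ComplexSubbands", "dtcwt_decompose", "dtcwt_reconstruct",
           "subband_features", "time_features"]

_WAVELET = "db6"


@dataclass
class ComplexSubbands:
    """Complex per-level coefficients (details[0] = level 1, finest).

    Coefficient arrays are cropped to the original sample support; the
    reflective padding used to suppress circular-wrap artifacts is kept
    only as bookkeeping (``pad_left``) for reconstruction.
    """

    details: List[np.ndarray]      # complex, undecimated, length n
    approx: np.ndarray             # complex approximation at the deepest level
    levels: int
    n: int                         # original (unpadded) sample count
    wavelet: str
    sampling_rate: float
    _padded: List[np.ndarray]      # real-branch coefficients incl. padding
    pad_left: int

    @property
    def interior(self) -> slice:
        """Coefficient span free of boundary contamination.

        Boundary coefficients see reflected data up to the filter support at
        the deepest level; statistics are computed on the interior so they
        do not depend on how the window happened to be cut.
        """
        support = (pywt.Wavelet(self.wavelet).dec_len - 1) * (2**self.levels - 1)
        m = min(support, self.n // 4)
        return slice(m, self.n - m)

    def magnitude_energy(self, level: int) -> float:
        """Sum of squared interior coefficient magnitudes at a level (1-based)."""
        return float(np.sum(np.abs(self.details[level - 1][self.interior]) ** 2))


def _reflect_pad(x: np.ndarray, block: int, margin: int):
    """Reflect both ends so wrap artifacts stay out of the signal support."""
    pad_left = margin
    total = len(x) + 2 * margin
    pad_right = margin + (-total) % block
    xp = np.pad(x, (pad_left, pad_right), mode="reflect")
    return xp, pad_left


def dtcwt_decompose(seg: SignalSegment, levels: int = 5) -> ComplexSubbands:
    """Complex multiresolution decomposition of a segment.

    The signal is reflect-padded on both sides (so the periodic wrap of the
    stationary transform never touches the analysed support); both branches
    (signal, Hilbert quadrature) are decomposed with the undecimated
    orthogonal transform and paired into complex coefficients, cropped back
    to the original support.
    """
    x = seg.samples
    if len(x) < 2**levels:
        raise BoundaryError(f"{len(x)} samples < 2**{levels}")
    block = 2**levels
    margin = 8 * block
    xp, pad = _reflect_pad(x, block, margin)
    xq = np.imag(hilbert(xp))
    re = pywt.swt(xp, _WAVELET, level=levels, trim_approx=True, norm=True)
    im = pywt.swt(xq, _WAVELET, level=levels, trim_approx=True, norm=True)
    n = len(x)
    sl = slice(pad, pad + n)
    # pywt returns [cA_n, cD_n, ..., cD_1]; reorder details finest-first
    approx = re[0][sl] + 1j * im[0][sl]
    details = [
        re[levels - k + 1][sl] + 1j * im[levels - k + 1][sl]
        for k in range(1, levels + 1)
    ]
    return ComplexSubbands(details, approx, levels, n, _WAVELET,
                           seg.sampling_rate, [np.asarray(c) for c in re], pad)


def dtcwt_reconstruct(sub: ComplexSubbands) -> np.ndarray:
    """Invert from the real branch; exact up to float roundoff."""
    xp = pywt.iswt(sub._padded, sub.wavelet, norm=True)
    return np.asarray(xp)[sub.pad_left: sub.pad_left + sub.n]


def subband_features(sub: ComplexSubbands) -> Dict[str, float]:
    """Flatten per-level magnitude statistics into named features.

    Names follow ``dtcwt_L{k}_{stat}`` with stats energy / meanmag /
    stdmag / entropy.  Entropy is the Shannon entropy of the normalized
    per-coefficient energy distribution (0 by convention for a zero level),
    which makes it invariant to amplitude scaling.
    """
    feats: Dict[str, float] = {}
    sl = sub.interior
    for k in range(1, sub.levels + 1):
        mag = np.abs(sub.details[k - 1][sl])
        e = float(np.sum(mag**2))
        feats[f"dtcwt_L{k}_energy"] = e
        feats[f"dtcwt_L{k}_meanmag"] = float(mag.mean())
        feats[f"dtcwt_L{k}_stdmag"] = float(mag.std())
        if e > 0:
            p = mag**2 / e
            nz = p[p > 0]
            feats[f"dtcwt_L{k}_entropy"] = float(-np.sum(nz * np.log(nz)))
        else:
            feats[f"dtcwt_L{k}_entropy"] = 0.0
    return feats


def time_features(seg: SignalSegment) -> Dict[str, float]:
    """Time-domain descriptors of a (detrended) segment.

    mean absolute amplitude and RMS in mV, peak-to-peak in mV,
    zero-crossing rate in 1/s, median absolute slope in mV/s.
    """
    x = seg.samples
    rate = seg.sampling_rate
    sign = np.sign(x)
    nz = sign != 0
    crossings = int(np.sum(np.diff(sign[nz]) != 0)) if nz.any() else 0
    return {
        "td_mean_abs": float(np.mean(np.abs(x))),
        "td_rms": float(np.sqrt(np.mean(x**2))),
        "td_p2p": float(x.max() - x.min()),
        "td_zcr": crossings / (len(x) / rate),
        "td_med_abs_slope": float(np.median(np.abs(np.diff(x)))) * rate,
    }
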