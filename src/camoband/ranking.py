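"""Stage 1 — spectral ranking of bands by two-class discriminability.

Each band image is split into two intensity classes by exact 1-D
two-means clustering (an optimal-threshold scan over the sorted pixel
values — deterministic, no seed).  The per-band discriminability

    D(b) = |mu1 - mu2| / (sigma1 + sigma2)

is large when the band separates the scene into two tight, well-spaced
intensity populations, exactly the signature of a camouflaged object
visible at that wavelength.  Candidate bands are local (or the global)
maxima of the smoothed discriminability curve, subject to a prominence
floor relative to the curve maximum.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cube_io import Hypercube

__all__ = [
    "D_CAP",
    "BandStats",
    "DiscriminabilityCurve",
    "TwoClassFit",
    "fit_two_classes",
    "discriminability",
    "build_curve",
    "select_candidates",
]

# Perfectly separated classes (zero total spread) rank above any finite D.
D_CAP = 1e6
_EPS_REL = 1e-12


class TwoClassFit(NamedTuple):
    """Result of the exact 1-D two-means split of a band image."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    threshold: float  # values <= threshold belong to the lower class
    degenerate: bool  # constant image: no two-class structure


def fit_two_classes(band_image: np.ndarray) -> TwoClassFit:
    """Exact two-means partition of the pixel intensities of one band.

    Scans every threshold between consecutive distinct sorted values and
    keeps the split minimising the within-class sum of squares (first
    minimiser on ties).  The class with the lower mean is reported
    first; sigmas are population standard deviations.  A constant image
    has no two-class structure and is returned with ``degenerate=True``.
    """
    x = np.sort(np.asarray(band_image, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty band image")
    if x[0] == x[-1]:
        v = float(x[0])
        return TwoClassFit(v, v, 0.0, 0.0, v, True)
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    k = np.arange(1, n)  # size of the lower class
    m1 = c1[:-1] / k
    m2 = (c1[-1] - c1[:-1]) / (n - k)
    ss1 = np.maximum(c2[:-1] - k * m1**2, 0.0)
    ss2 = np.maximum((c2[-1] - c2[:-1]) - (n - k) * m2**2, 0.0)
    wcss = ss1 + ss2
    wcss[x[1:] == x[:-1]] = np.inf  # only split between distinct values
    kbest = int(np.argmin(wcss))  # first minimiser on ties
    mu1, mu2 = float(m1[kbest]), float(m2[kbest])
    s1 = float(np.sqrt(ss1[kbest] / (kbest + 1)))
    s2 = float(np.sqrt(ss2[kbest] / (n - kbest - 1)))
    threshold = float(0.5 * (x[kbest] + x[kbest + 1]))
    return TwoClassFit(mu1, mu2, s1, s2, threshold, False)


def discriminability(mu1: float, mu2: float, sigma1: float, sigma2: float) -> float:
    """Two-class discriminability D = |mu1 - mu2| / (sigma1 + sigma2).

    Equal means give 0 regardless of spread.  When the total spread is
    negligible relative to the mean gap (below ``1e-12`` of it) the
    classes are perfectly separated and D is capped at :data:`D_CAP`
    rather than diverging; any finite ratio above the cap is clipped to
    it as well, so the cap is a true maximum of the scale.
    """
    for v in (mu1, mu2, sigma1, sigma2):
        if not np.isfinite(v):
            raise ValueError("class statistics must be finite")
    num = abs(mu1 - mu2)
    if num == 0.0:
        return 0.0
    denom = sigma1 + sigma2
    if denom <= _EPS_REL * num:
        return D_CAP
    return min(num / denom, D_CAP)


@dataclass
class BandStats:
    """Per-band two-class statistics and discriminability."""

    band_index: int
    wavelength: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    d_value: float
    degenerate: bool = False


@dataclass
class DiscriminabilityCurve:
    """The band discriminability curve with its selected candidates."""

    stats: list[BandStats]
    smoothing_window: int
    candidates: list[int]

    @property
    def d_values(self) -> np.ndarray:
        return np.array([s.d_value for s in self.stats])

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([s.wavelength for s in self.stats])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "band_index": [s.band_index for s in self.stats],
                "wavelength_nm": np.round(self.wavelengths, 1),
                "mu1": [s.mu1 for s in self.stats],
                "mu2": [s.mu2 for s in self.stats],
                "sigma1": [s.sigma1 for s in self.stats],
                "sigma2": [s.sigma2 for s in self.stats],
                "d_value": self.d_values,
            }
        )
        df["is_candidate"] = df["band_index"].isin(self.candidates)
        return df


# ---------------------------------------------------------------------------
# Peak machinery (shared with the PCA baseline)
# ---------------------------------------------------------------------------

def smooth_curve(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with truncated edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    n = values.size
    if window == 1 or n == 0:
        return values.copy()
    h = window // 2
    c = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - h)
    hi = np.minimum(n, idx + h + 1)
    return (c[hi] - c[lo]) / (hi - lo)


def local_maxima(values: np.ndarray) -> list[int]:
    """Indices of local maxima, plateau runs reported at their leftmost
    index.  A curve endpoint (or a plateau touching it) is eligible only
    if it strictly exceeds its two nearest inward values, so a flat tail
    never produces a spurious edge peak; a constant curve has none."""
    values = np.asarray(values, dtype=float)
    n = values.size
    peaks: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        v = values[i]
        if i == 0 and j == n - 1:
            pass  # constant curve
        elif i == 0 or j == n - 1:
            inward = values[j + 1 : j + 3] if i == 0 else values[max(i - 2, 0) : i]
            if inward.size and np.all(v > inward):
                peaks.append(i)
        elif values[i - 1] < v and values[j + 1] < v:
            peaks.append(i)
        i = j + 1
    return peaks


def peak_prominence(values: np.ndarray, peak: int) -> float:
    """Topographic prominence of ``values[peak]``: height above the higher
    of the two lowest points separating it from higher terrain (or from
    the curve ends if no higher terrain exists on that side)."""
    values = np.asarray(values, dtype=float)
    v = values[peak]
    bases = []
    for sl in (values[:peak][::-1], values[peak + 1 :]):
        higher = np.flatnonzero(sl > v)
        stretch = sl[: higher[0]] if higher.size else sl
        # a side with no terrain at all (edge peak) imposes no bound
        bases.append(stretch.min() if stretch.size else -np.inf)
    base = max(bases)
    return float(v - base) if np.isfinite(base) else float(v - values.min())


def select_peaks(
    values: np.ndarray,
    mode: str = "local_maxima",
    smoothing_window: int = 5,
    min_prominence_fraction: float = 0.1,
    floor_reference: float | None = None,
) -> list[int]:
    """Smooth ``values`` and return peak indices in index order.

    In ``local_maxima`` mode, peaks must have prominence at least
    ``min_prominence_fraction`` times ``floor_reference`` (the smoothed
    curve's maximum when not given).  ``global_maximum`` mode returns the
    single argmax of the smoothed curve (smallest index on ties).  An
    empty result is a valid outcome, not an error.
    """
    if not 0.0 <= min_prominence_fraction <= 1.0:
        raise ValueError("min_prominence_fraction must be in [0, 1]")
    sm = smooth_curve(values, smoothing_window)
    if sm.size == 0:
        return []
    if mode == "global_maximum":
        return [int(np.argmax(sm))]
    if mode != "local_maxima":
        raise ValueError(f"unknown candidate mode '{mode}'")
    ref = float(sm.max()) if floor_reference is None else float(floor_reference)
    floor = min_prominence_fraction * ref
    return [p for p in local_maxima(sm) if peak_prominence(sm, p) >= floor]


# ---------------------------------------------------------------------------
# Curve construction
# ---------------------------------------------------------------------------

def build_curve(
    cube: Hypercube,
    mode: str = "local_maxima",
    smoothing_window: int = 5,
    min_prominence_fraction: float = 0.1,
) -> DiscriminabilityCurve:
    """Fit two classes per band, compute D(b), and select candidates.

    Degenerate (constant) bands get D = 0.  Candidates are stored in
    wavelength order.
    """
    stats: list[BandStats] = []
    for b in range(cube.n_bands):
        fit = fit_two_classes(cube.band(b))
        d = 0.0 if fit.degenerate else discriminability(fit.mu1, fit.mu2, fit.sigma1, fit.sigma2)
        stats.append(
            BandStats(
                band_index=b,
                wavelength=float(cube.wavelengths[b]),
                mu1=fit.mu1,
                mu2=fit.mu2,
                sigma1=fit.sigma1,
                sigma2=fit.sigma2,
                d_value=d,
                degenerate=fit.degenerate,
            )
        )
    d_values = np.array([s.d_value for s in stats])
    candidates = select_peaks(
        d_values,
        mode=mode,
        smoothing_window=min(smoothing_window, _largest_odd(cube.n_bands)),
        min_prominence_fraction=min_prominence_fraction,
    )
    return DiscriminabilityCurve(stats=stats, smoothing_window=smoothing_window, candidates=candidates)


def _largest_odd(n: int) -> int:
    return n if n % 2 == 1 else n - 1


def select_candidates(
    curve: DiscriminabilityCurve | np.ndarray | Sequence[float],
    mode: str = "local_maxima",
    smoothing_window: int = 5,
    min_prominence_fraction: float = 0.1,
) -> list[int]:
    """Candidate band indices from a discriminability curve (or raw values)."""
    values = curve.d_values if isinstance(curve, DiscriminabilityCurve) else np.asarray(curve, float)
    return select_peaks(
        values,
        mode=mode,
        smoothing_window=smoothing_window,
        min_prominence_fraction=min_prominence_fraction,
    )
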