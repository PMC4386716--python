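"""Stage 2 — spatial pruning of candidate bands by region entropy.

A good band splits the scene into two coherent regions: the camouflaged
object and the background.  A spatially noisy band produces the same
two *intensity* classes but shatters them into many small spatial
fragments.  Each candidate band is binarised by the stage-1 two-means
split, connected components are counted within each binary class, and
the Shannon entropy of the pixel-share distribution over the M regions

    H(b) = -sum_i p_i log2 p_i,   p_i = N_i / (S x L)

quantifies that fragmentation.  The ideal segmentation (two regions)
has H <= 1 bit, which is why the working threshold is about 1; bands
above the threshold are discarded.

Entropy is measured in bits so the threshold value 1 coincides exactly
with the entropy of an equal two-region split.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cube_io import Hypercube
from .ranking import fit_two_classes

__all__ = [
    "SegmentationResult",
    "BandSelection",
    "segment_band",
    "region_entropy",
    "prune",
]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def region_entropy(region_sizes: Sequence[int] | np.ndarray, total_pixels: int) -> float:
    """Shannon entropy (bits) of the pixel-share distribution over regions.

    ``region_sizes`` must be nonempty, positive, and sum to
    ``total_pixels`` (every pixel belongs to exactly one region).
    """
    sizes = np.asarray(region_sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("region_sizes must be nonempty")
    if np.any(sizes <= 0):
        raise ValueError("region sizes must be positive")
    if int(sizes.sum()) != int(total_pixels):
        raise ValueError(
            f"region sizes sum to {int(sizes.sum())}, expected {int(total_pixels)} pixels"
        )
    p = sizes / total_pixels
    return float(-(p * np.log2(p)).sum())


@dataclass
class SegmentationResult:
    """Connected-component segmentation of one band's binary split."""

    band_index: int
    labels: np.ndarray  # region labels 1..M over (line, sample)
    region_sizes: np.ndarray  # pixels per region, index i-1 -> region i
    region_count: int
    entropy: float  # bits


def segment_band(
    band_image: np.ndarray,
    connectivity: int = 8,
    band_index: int = -1,
) -> SegmentationResult:
    """Binarise a band by its two-means split and count spatial regions.

    Connected components are labelled within each binary class
    separately (default 8-connectivity) and numbered 1..M across both
    classes; a constant image is a single region with zero entropy.
    """
    img = np.asarray(band_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("band image must be 2-D")
    structure = _structure(connectivity)
    fit = fit_two_classes(img)
    if fit.degenerate:
        labels = np.ones(img.shape, dtype=np.int32)
        return SegmentationResult(band_index, labels, np.array([img.size]), 1, 0.0)
    upper = img > fit.threshold
    lab_low, n_low = ndimage.label(~upper, structure=structure)
    lab_high, n_high = ndimage.label(upper, structure=structure)
    labels = np.where(upper, lab_high + n_low, lab_low).astype(np.int32)
    m = n_low + n_high
    sizes = np.bincount(labels.ravel(), minlength=m + 1)[1:]
    entropy = region_entropy(sizes, img.size)
    return SegmentationResult(band_index, labels, sizes, m, entropy)


@dataclass
class BandSelection:
    """Outcome of entropy pruning over the stage-1 candidates."""

    candidates: list[int]
    entropies: list[float]  # aligned with candidates, bits
    threshold: float  # bits
    selected: list[int]
    rejected: list[tuple[int, float]]  # (band index, entropy)
    region_counts: list[int] = field(default_factory=list)
    fallback: bool = False  # no band passed; lowest-entropy candidate kept

    def to_frame(self, cube: Hypercube | None = None, d_values=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "band_index": self.candidates,
                "entropy_bits": self.entropies,
                "region_count": self.region_counts or [np.nan] * len(self.candidates),
            }
        )
        if cube is not None:
            df.insert(1, "wavelength_nm", np.round(cube.wavelengths[self.candidates], 1))
        if d_values is not None:
            d_values = np.asarray(d_values)
            df["d_value"] = d_values[self.candidates]
        df["kept"] = df["band_index"].isin(self.selected)
        return df


def prune(
    candidates: Sequence[int],
    cube: Hypercube,
    threshold: float = 1.0,
    connectivity: int = 8,
) -> BandSelection:
    """Discard candidate bands whose region entropy exceeds ``threshold``.

    Survivors keep stage-1 wavelength order.  If no candidate passes,
    the single lowest-entropy candidate is retained (the detector needs
    at least one band) and the selection is flagged as a fallback.
    """
    candidates = [int(b) for b in candidates]
    if not candidates:
        raise ValueError("candidates must be nonempty")
    entropies: list[float] = []
    counts: list[int] = []
    for b in candidates:
        seg = segment_band(cube.band(b), connectivity=connectivity, band_index=b)
        entropies.append(seg.entropy)
        counts.append(seg.region_count)
    selected = [b for b, h in zip(candidates, entropies) if h <= threshold]
    fallback = False
    if not selected:
        selected = [candidates[int(np.argmin(entropies))]]
        fallback = True
    rejected = [(b, h) for b, h in zip(candidates, entropies) if b not in selected]
    return BandSelection(
        candidates=candidates,
        entropies=entropies,
        threshold=threshold,
        selected=selected,
        rejected=rejected,
        region_counts=counts,
        fallback=fallback,
    )
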