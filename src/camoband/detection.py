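"""Final stage — camouflaged-region detection by K-means on selected bands.

Each pixel is represented by its intensity vector over the selected
bands (standardised per band), clustered into two groups by Lloyd's
algorithm with a deterministic initialisation, and the minority cluster
is reported as the camouflaged region: in every scenario this method
targets, the camouflaged object occupies less area than its background.
The whole path is seed-free — identical inputs give identical masks.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .cube_io import Hypercube
from .pruning import BandSelection
from .ranking import fit_two_classes

__all__ = ["DetectionResult", "detect", "detect_profile_baseline"]


@dataclass
class DetectionResult:
    """Binary camouflage mask plus the raw two-way pixel labelling."""

    mask: np.ndarray  # (line, sample), uint8, 1 = camouflaged
    cluster_labels: np.ndarray  # (line, sample), int
    bands_used: list[int]
    target_cluster_rule: str  # how the positive cluster was chosen

    @property
    def n_positive(self) -> int:
        return int(self.mask.sum())


def _as_band_list(selection: BandSelection | Sequence[int]) -> list[int]:
    bands = selection.selected if isinstance(selection, BandSelection) else list(selection)
    # dedupe + sort: makes the result invariant to band-order permutations
    return sorted({int(b) for b in bands})


def _minority_positive(labels: np.ndarray, features: np.ndarray) -> tuple[int, str]:
    """Pick the positive cluster: minority by pixel count; on a tie, the
    cluster whose pixels lie further (on average) from the global
    feature mean."""
    counts = np.bincount(labels, minlength=2)
    if counts[0] != counts[1]:
        return int(np.argmin(counts)), "minority"
    center = features.mean(axis=0)
    dists = np.linalg.norm(features - center, axis=1)
    mean_d = [dists[labels == c].mean() for c in (0, 1)]
    return int(np.argmax(mean_d)), "tie:distance-from-mean"


def detect(cube: Hypercube, selection: BandSelection | Sequence[int]) -> DetectionResult:
    """Cluster pixels over the selected bands and return the camouflage mask.

    Bands are standardised to zero mean / unit variance (constant bands
    contribute nothing), then two-means clustered with centroids
    initialised at the pixels holding the lowest and highest intensity
    of the lowest-index non-constant selected band.  A single selected
    band degenerates gracefully to the exact 1-D two-means split of
    that band.
    """
    bands = _as_band_list(selection)
    if not bands:
        raise ValueError("selection must contain at least one band")
    if max(bands) >= cube.n_bands or min(bands) < 0:
        raise ValueError("selected band index out of range")
    L, S = cube.n_lines, cube.n_samples

    if len(bands) == 1:
        img = np.asarray(cube.band(bands[0]), dtype=float)
        fit = fit_two_classes(img)
        if fit.degenerate:
            zeros = np.zeros((L, S), dtype=np.uint8)
            return DetectionResult(zeros, zeros.astype(int), bands, "degenerate")
        labels = (img > fit.threshold).astype(int)
        feats = img.reshape(-1, 1)
        pos, rule = _minority_positive(labels.ravel(), feats)
        mask = (labels == pos).astype(np.uint8)
        return DetectionResult(mask, labels, bands, rule)

    X = cube.data[:, :, bands].reshape(-1, len(bands)).astype(float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    nonconst = std > 0
    Z = np.zeros_like(X)
    Z[:, nonconst] = (X[:, nonconst] - mean[nonconst]) / std[nonconst]

    init = _initial_centroids(X, Z, nonconst)
    if init is None:  # all pixels identical in feature space
        zeros = np.zeros((L, S), dtype=np.uint8)
        return DetectionResult(zeros, zeros.astype(int), bands, "degenerate")

    km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=300, tol=1e-8, random_state=0)
    labels = km.fit_predict(Z)
    pos, rule = _minority_positive(labels, Z)
    mask = (labels == pos).astype(np.uint8).reshape(L, S)
    return DetectionResult(mask, labels.reshape(L, S), bands, rule)


def _initial_centroids(X: np.ndarray, Z: np.ndarray, nonconst: np.ndarray) -> np.ndarray | None:
    """Deterministic seed centroids: the standardised feature vectors of
    the pixels with the lowest and highest intensity in the first
    non-constant band; falls back to the extremes of the feature-vector
    norm if those two vectors coincide."""
    for j in range(X.shape[1]):
        if nonconst[j]:
            lo, hi = int(np.argmin(X[:, j])), int(np.argmax(X[:, j]))
            init = Z[[lo, hi]]
            if not np.array_equal(init[0], init[1]):
                return init
            break
    norms = np.linalg.norm(Z, axis=1)
    lo, hi = int(np.argmin(norms)), int(np.argmax(norms))
    init = Z[[lo, hi]]
    if np.array_equal(init[0], init[1]):
        return None
    return init


def detect_profile_baseline(cube: Hypercube) -> DetectionResult:
    """Baseline: cluster on the full B-band spectral profile of every pixel."""
    return detect(cube, list(range(cube.n_bands)))
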