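"""PCA loading-curve band selection — the classical comparison method.

Principal components are computed over the mean-centred pixel spectra;
the chosen component's loading curve (its per-band weights) is scanned
for local maxima *and* minima with the same smoothing/prominence
machinery as the discriminability curve, and the extrema become the
selected bands.  Unlike the spectral-spatial method this needs a human
(or a config default) to pick which component exposes the anomaly; the
conventional choice is the second component, since the first mostly
carries overall brightness.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cube_io import Hypercube
from .ranking import select_peaks, smooth_curve

__all__ = ["PcaSelection", "pca_band_selection"]


@dataclass
class PcaSelection:
    """Bands picked at the extrema of one principal component's loadings."""

    component_index: int  # requested, 1-based
    used_component: int  # actually used after rank clamping, 0 if none
    loadings: np.ndarray  # length B (zeros when degenerate)
    selected: list[int]
    explained_variance_ratio: np.ndarray

    def to_frame(self, cube: Hypercube | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"band_index": np.arange(self.loadings.size), "loading": self.loadings}
        )
        if cube is not None:
            df.insert(1, "wavelength_nm", np.round(cube.wavelengths, 1))
        df["is_selected"] = df["band_index"].isin(self.selected)
        return df


def pca_band_selection(
    cube: Hypercube,
    component_index: int = 2,
    smoothing_window: int = 5,
    min_prominence_fraction: float = 0.1,
) -> PcaSelection:
    """Select bands at the loading-curve extrema of one principal component.

    ``component_index`` is 1-based.  If the requested component has no
    variance (rank-deficient data) the index is clamped to the highest
    informative component with a warning; a constant cube has rank zero
    and yields an empty selection.  Loadings are sign-normalised so the
    largest-magnitude loading is positive.
    """
    B = cube.n_bands
    n_pix = cube.n_lines * cube.n_samples
    if not 1 <= component_index <= min(B, n_pix):
        raise ValueError(
            f"component_index must be in [1, {min(B, n_pix)}], got {component_index}"
        )
    X = cube.data.reshape(n_pix, B).astype(float)
    n_comp = min(B, n_pix, component_index + 4)
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(X)
    total_var = pca.explained_variance_.sum()
    if total_var <= 0 or not np.isfinite(total_var):
        rank = 0
    else:
        rank = int(np.sum(pca.explained_variance_ > 1e-10 * total_var))
    if rank == 0:
        warnings.warn("constant cube: PCA is degenerate, empty band selection", stacklevel=2)
        return PcaSelection(
            component_index, 0, np.zeros(B), [], pca.explained_variance_ratio_
        )
    used = component_index
    if used > rank:
        used = rank
        warnings.warn(
            f"component {component_index} has no variance (rank {rank}); using component {used}",
            stacklevel=2,
        )
    loadings = pca.components_[used - 1].copy()
    if loadings[int(np.argmax(np.abs(loadings)))] < 0:
        loadings = -loadings
    window = min(smoothing_window, B if B % 2 == 1 else B - 1)
    ref = float(np.abs(smooth_curve(loadings, window)).max())
    maxima = select_peaks(
        loadings, "local_maxima", window, min_prominence_fraction, floor_reference=ref
    )
    minima = select_peaks(
        -loadings, "local_maxima", window, min_prominence_fraction, floor_reference=ref
    )
    selected = sorted(set(maxima) | set(minima))
    return PcaSelection(
        component_index, used, loadings, selected, pca.explained_variance_ratio_
    )
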