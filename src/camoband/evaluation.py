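"""Detection-rate / false-alarm-rate evaluation and the method comparison harness.

Rates are pixel-level and reported in percent:

    DR  = 100 * tp / (tp + fn)      (fraction of camouflaged pixels found)
    FAR = 100 * fp / (fp + tn)      (fraction of background pixels raised)

``compare_methods`` runs the four detectors the package ships — the PCA
loading-curve baseline, the full-spectrum profile baseline, spectral-only
selection ("Proposed 1": candidates straight to the detector) and
spectral + spatial selection ("Proposed 2": candidates pruned by region
entropy first) — on one cube and tabulates DR, FAR and band count.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import pca_band_selection
from .config import PipelineConfig
from .cube_io import GroundTruthMask, Hypercube
from .detection import DetectionResult, detect, detect_profile_baseline
from .pruning import prune
from .ranking import build_curve, select_peaks

__all__ = ["EvalMetrics", "evaluate", "compare_methods", "format_table"]

METHODS = ("PCA", "Profile", "Proposed 1", "Proposed 2")


@dataclass
class EvalMetrics:
    """Pixel-level confusion counts and the derived rates (percent)."""

    dr: float  # NaN when the truth has no positive pixels
    far: float
    n_bands: int
    tp: int
    fp: int
    fn: int
    tn: int


def evaluate(
    mask: DetectionResult | np.ndarray,
    truth: GroundTruthMask | np.ndarray,
    n_bands: int | None = None,
) -> EvalMetrics:
    """Score a detection mask against ground truth.

    DR is undefined (NaN) when the truth contains no positive pixels;
    FAR is likewise NaN with no negatives.
    """
    if isinstance(mask, DetectionResult):
        if n_bands is None:
            n_bands = len(mask.bands_used)
        mask = mask.mask
    mask = np.asarray(mask).astype(bool)
    t = truth.mask if isinstance(truth, GroundTruthMask) else np.asarray(truth)
    t = t.astype(bool)
    if mask.shape != t.shape:
        raise ValueError(f"mask shape {mask.shape} does not match truth shape {t.shape}")
    tp = int(np.sum(mask & t))
    fp = int(np.sum(mask & ~t))
    fn = int(np.sum(~mask & t))
    tn = int(np.sum(~mask & ~t))
    dr = 100.0 * tp / (tp + fn) if tp + fn else math.nan
    far = 100.0 * fp / (fp + tn) if fp + tn else math.nan
    return EvalMetrics(dr=dr, far=far, n_bands=n_bands or 0, tp=tp, fp=fp, fn=fn, tn=tn)


def _proposed_candidates(cube: Hypercube, config: PipelineConfig) -> list[int]:
    curve = build_curve(
        cube,
        mode=config.candidate_mode,
        smoothing_window=config.smoothing_window,
        min_prominence_fraction=config.min_prominence_fraction,
    )
    candidates = curve.candidates
    if not candidates:  # flat curve: fall back to the global maximum
        candidates = select_peaks(
            curve.d_values, "global_maximum", min(config.smoothing_window, cube.n_bands - (1 - cube.n_bands % 2))
        )
    return candidates


def compare_methods(
    cube: Hypercube,
    truth: GroundTruthMask,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Run all four detectors on one cube and tabulate DR / FAR / band count.

    Rows: ``PCA``, ``Profile``, ``Proposed 1``, ``Proposed 2``.
    Deterministic given the cube and config.
    """
    config = config or PipelineConfig()
    rows: dict[str, EvalMetrics] = {}

    pca_sel = pca_band_selection(
        cube,
        component_index=config.pca_component,
        smoothing_window=config.smoothing_window,
        min_prominence_fraction=config.min_prominence_fraction,
    )
    if pca_sel.selected:
        pca_det = detect(cube, pca_sel.selected)
    else:
        zeros = np.zeros((cube.n_lines, cube.n_samples), dtype=np.uint8)
        pca_det = DetectionResult(zeros, zeros.astype(int), [], "degenerate")
    rows["PCA"] = evaluate(pca_det, truth)

    rows["Profile"] = evaluate(detect_profile_baseline(cube), truth)

    candidates = _proposed_candidates(cube, config)
    rows["Proposed 1"] = evaluate(detect(cube, candidates), truth)

    selection = prune(
        candidates, cube, threshold=config.entropy_threshold_bits, connectivity=config.connectivity
    )
    rows["Proposed 2"] = evaluate(detect(cube, selection), truth)

    return pd.DataFrame(
        {
            "dr_pct": [rows[m].dr for m in METHODS],
            "far_pct": [rows[m].far for m in METHODS],
            "n_bands": [rows[m].n_bands for m in METHODS],
            "tp": [rows[m].tp for m in METHODS],
            "fp": [rows[m].fp for m in METHODS],
            "fn": [rows[m].fn for m in METHODS],
            "tn": [rows[m].tn for m in METHODS],
        },
        index=pd.Index(METHODS, name="method"),
    )


def format_table(table: pd.DataFrame) -> str:
    """Plain-text comparison table: Method / DR (%) / FAR (%) / bands."""
    lines = [f"{'Method':<12} {'DR (%)':>8} {'FAR (%)':>9} {'Bands':>6}"]
    for method, row in table.iterrows():
        dr = "n/a" if math.isnan(row["dr_pct"]) else f"{row['dr_pct']:.1f}"
        far = "n/a" if math.isnan(row["far_pct"]) else f"{row['far_pct']:.4g}"
        lines.append(f"{method:<12} {dr:>8} {far:>9} {int(row['n_bands']):>6}")
    return "\n".join(lines) + "\n"
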