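"""End-to-end spectral-spatial detection pipeline and its run artifacts."""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .cube_io import Hypercube, write_mask
from .detection import DetectionResult, detect
from .pruning import BandSelection, prune
from .ranking import DiscriminabilityCurve, build_curve, select_peaks

__all__ = ["PipelineResult", "run_pipeline", "write_artifacts"]


@dataclass
class PipelineResult:
    """Everything one spectral-spatial run produces."""

    curve: DiscriminabilityCurve
    selection: BandSelection
    detection: DetectionResult
    config: PipelineConfig


def run_pipeline(cube: Hypercube, config: PipelineConfig | None = None) -> PipelineResult:
    """Full spectral + spatial path: rank bands, prune by region entropy,
    detect by two-means on the survivors.

    If no local maximum clears the prominence floor (a featureless
    curve), the global maximum is used so the detector always receives
    at least one band.
    """
    config = config or PipelineConfig()
    curve = build_curve(
        cube,
        mode=config.candidate_mode,
        smoothing_window=config.smoothing_window,
        min_prominence_fraction=config.min_prominence_fraction,
    )
    candidates = curve.candidates
    if not candidates:
        window = min(config.smoothing_window, cube.n_bands - (1 - cube.n_bands % 2))
        candidates = select_peaks(curve.d_values, "global_maximum", max(window, 1))
    selection = prune(
        candidates,
        cube,
        threshold=config.entropy_threshold_bits,
        connectivity=config.connectivity,
    )
    detection = detect(cube, selection)
    return PipelineResult(curve=curve, selection=selection, detection=detection, config=config)


def write_artifacts(result: PipelineResult, cube: Hypercube, out_dir: str | Path) -> dict[str, Path]:
    """Write the run's artifacts: curve CSV, pruning report CSV, mask PNG,
    JSON summary (wavelengths in nm, 1 decimal).  Byte-deterministic for
    identical inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "curve": out / "curve.csv",
        "pruning": out / "pruning.csv",
        "mask": out / "mask.png",
        "summary": out / "summary.json",
    }
    result.curve.to_frame().to_csv(paths["curve"], index=False)
    result.selection.to_frame(cube, d_values=result.curve.d_values).to_csv(
        paths["pruning"], index=False
    )
    write_mask(result.detection.mask, paths["mask"])
    wl = np.asarray(cube.wavelengths)
    summary = {
        "config": result.config.to_dict(),
        "candidate_bands": result.selection.candidates,
        "candidate_wavelengths_nm": [round(float(wl[b]), 1) for b in result.selection.candidates],
        "selected_bands": result.selection.selected,
        "selected_wavelengths_nm": [round(float(wl[b]), 1) for b in result.selection.selected],
        "entropies_bits": [round(h, 6) for h in result.selection.entropies],
        "entropy_threshold_bits": result.selection.threshold,
        "fallback_used": result.selection.fallback,
        "target_cluster_rule": result.detection.target_cluster_rule,
        "n_detected_pixels": result.detection.n_positive,
    }
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return paths
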