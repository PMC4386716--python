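"""Synthetic VNIR scene generator with a planted camouflaged region.

Emulates, at desk scale, what a pushbroom VNIR line scanner sees when a
minority object spectrally mimics its background: two reflectance
spectra that agree everywhere except inside controllable wavelength
windows, modulated by an optional illumination ramp, perturbed by
additive Gaussian sensor noise, and quantised to the sensor bit depth.
The planted mask gives every downstream stage a ground-truth surface.

Reflectance spectra are sums of Gaussian bumps over a baseline.  The
``leaf_scene`` factory packages a leaf-like background (green reflectance
bump plus a broad near-infrared shoulder) with a foreground that differs
only by narrow bumps in the requested windows — the printed-leaf-among-
real-leaves scenario in miniature.

Randomness is split into three independent streams spawned from the one
scene seed — target-shape rasterisation, sensor noise, noisy-band
injection — so enabling one feature never perturbs the draws of another.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .cube_io import GroundTruthMask, Hypercube

__all__ = [
    "SpectrumModel",
    "SceneSpec",
    "make_cube",
    "separation_profile",
    "planted_window",
    "leaf_scene",
    "scene_from_config",
    "scene_to_config",
]


@dataclass(frozen=True)
class SpectrumModel:
    """Reflectance spectrum: baseline plus Gaussian bumps, clipped to [0, 1].

    ``bumps`` are ``(center_nm, width_nm, amplitude)`` triples; width is
    the Gaussian sigma.
    """

    baseline: float
    bumps: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        for center, width, _amp in self.bumps:
            if width <= 0:
                raise ValueError(f"bump width must be > 0, got {width} at {center} nm")

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        refl = np.full_like(wl, self.baseline)
        for center, width, amp in self.bumps:
            refl = refl + amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return np.clip(refl, 0.0, 1.0)

    def with_bumps(self, extra: Sequence[tuple[float, float, float]]) -> "SpectrumModel":
        return SpectrumModel(self.baseline, self.bumps + tuple(extra))


# Leaf-like background: green reflectance bump near 550 nm and a broad
# NIR shoulder past the red edge.
LEAF_BACKGROUND = SpectrumModel(0.22, ((550.0, 30.0, 0.12), (780.0, 130.0, 0.45)))


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scene; identical spec -> identical cube."""

    lines: int = 64
    samples: int = 64
    bands: int = 100
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    background: SpectrumModel = LEAF_BACKGROUND
    foreground: SpectrumModel = LEAF_BACKGROUND
    target_shape: str = "ellipse"
    target_area_fraction: float = 0.1
    noise_sd: float = 32.0
    illumination_gradient: float = 0.0
    bit_depth: int = 12
    seed: int = 0
    noisy_bands: int = 0

    def __post_init__(self) -> None:
        if min(self.lines, self.samples, self.bands) < 1:
            raise ValueError("scene dimensions must be positive")
        if not 0 < self.target_area_fraction < 0.5:
            raise ValueError("target_area_fraction must lie in (0, 0.5): the camouflaged region is the minority class")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.target_shape not in ("rectangle", "ellipse", "blob"):
            raise ValueError(f"unknown target_shape '{self.target_shape}'")
        if self.wavelength_range[1] <= self.wavelength_range[0]:
            raise ValueError("wavelength_range must be increasing")
        if self.bit_depth < 1 or self.bit_depth > 16:
            raise ValueError("bit_depth must be in [1, 16]")
        if self.noisy_bands < 0 or self.noisy_bands > self.bands:
            raise ValueError("noisy_bands must be in [0, bands]")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range
        if self.bands == 1:
            return np.array([lo])
        return np.linspace(lo, hi, self.bands)

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1


def _rasterize_target(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    L, S = spec.lines, spec.samples
    area = spec.target_area_fraction * L * S
    yy, xx = np.mgrid[0:L, 0:S]
    cy, cx = (L - 1) / 2.0, (S - 1) / 2.0
    if spec.target_shape == "rectangle":
        h = max(1, int(round(np.sqrt(area / 1.5))))
        w = max(1, int(round(area / h)))
        y0, x0 = int(cy - h / 2), int(cx - w / 2)
        mask = np.zeros((L, S), dtype=bool)
        mask[max(0, y0) : y0 + h, max(0, x0) : x0 + w] = True
        return mask
    if spec.target_shape == "ellipse":
        # semi-axes with 1.3 aspect; pi*a*b = area
        a = np.sqrt(area / (np.pi * 1.3))
        b = 1.3 * a
        return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    # blob: smoothed noise biased toward the centre, thresholded at the
    # requested area quantile; keep the largest connected component.
    field_ = rng.normal(size=(L, S))
    field_ = ndimage.gaussian_filter(field_, sigma=min(L, S) / 8.0)
    r2 = ((yy - cy) / (L / 2.0)) ** 2 + ((xx - cx) / (S / 2.0)) ** 2
    field_ = field_ / max(field_.std(), 1e-12) + 2.0 * np.exp(-2.0 * r2)
    thresh = np.quantile(field_, 1.0 - spec.target_area_fraction)
    mask = field_ > thresh
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def make_cube(spec: SceneSpec) -> tuple[Hypercube, GroundTruthMask]:
    """Render the scene: (cube, ground-truth mask).

    Pixels inside the mask carry the foreground spectrum, outside the
    background spectrum; each is scaled by a linear illumination ramp
    across the sample axis, perturbed by i.i.d. Gaussian noise of sd
    ``noise_sd`` (sensor counts), and quantised to ``bit_depth`` by
    rounding and saturation.
    """
    shape_rng, noise_rng, noisy_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(3)
    )
    wl = spec.wavelengths
    bg = spec.background(wl)
    fg = spec.foreground(wl)
    if spec.noise_sd == 0 and np.array_equal(bg, fg) and spec.noisy_bands == 0:
        warnings.warn(
            "degenerate scene: foreground and background spectra are identical "
            "at every band and noise_sd is 0 — there is nothing to detect",
            stacklevel=2,
        )
    mask = _rasterize_target(spec, shape_rng)
    refl = np.where(mask[:, :, None], fg[None, None, :], bg[None, None, :])
    ramp = 1.0 + spec.illumination_gradient * (
        np.arange(spec.samples) / max(spec.samples - 1, 1) - 0.5
    )
    intensity = refl * spec.full_scale * ramp[None, :, None]
    if spec.noise_sd > 0:
        intensity = intensity + noise_rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    noisy_idx: list[int] = []
    if spec.noisy_bands:
        noisy_idx = sorted(
            int(i) for i in noisy_rng.choice(spec.bands, size=spec.noisy_bands, replace=False)
        )
        delta = 8.0 * spec.noise_sd if spec.noise_sd > 0 else 0.2 * spec.full_scale
        mid = 0.5 * spec.full_scale
        for b in noisy_idx:
            signs = noisy_rng.choice([-1.0, 1.0], size=(spec.lines, spec.samples))
            jitter = (
                noisy_rng.normal(0.0, spec.noise_sd, size=signs.shape) if spec.noise_sd > 0 else 0.0
            )
            intensity[:, :, b] = mid + signs * delta + jitter
    data = np.clip(np.rint(intensity), 0, spec.full_scale).astype(np.uint16)
    meta = {"bit_depth": spec.bit_depth, "seed": spec.seed, "noisy_bands": noisy_idx}
    return Hypercube(data, wl, meta), GroundTruthMask(mask.astype(np.uint8))


def separation_profile(spec: SceneSpec) -> np.ndarray:
    """Per-band expected class separation |fg - bg| * full_scale / (2 * noise_sd).

    The oracle for where the discriminability curve should peak; requires
    ``noise_sd > 0`` (a noiseless scene has infinite separation wherever
    the spectra differ).
    """
    if spec.noise_sd <= 0:
        raise ValueError("separation_profile is undefined for noise_sd = 0")
    wl = spec.wavelengths
    return np.abs(spec.foreground(wl) - spec.background(wl)) * spec.full_scale / (2.0 * spec.noise_sd)


def planted_window(spec: SceneSpec, rel_height: float = 0.5) -> np.ndarray:
    """Band indices where the expected separation is >= ``rel_height`` of its peak."""
    prof = separation_profile(spec)
    if prof.max() == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(prof >= rel_height * prof.max())


def leaf_scene(
    seed: int = 0,
    separation: float = 5.0,
    window_centers_nm: Sequence[float] = (700.0,),
    window_width_nm: float = 25.0,
    noise_sd: float = 32.0,
    noisy_bands: int = 0,
    **overrides,
) -> SceneSpec:
    """Default desk-scale scene: leaf-like background, foreground differing
    only by Gaussian bumps at ``window_centers_nm``.

    ``separation`` sets the expected per-band class separation at each
    window centre (in :func:`separation_profile` units), i.e. the bump
    amplitude is ``separation * 2 * noise_sd / full_scale``.
    """
    spec = SceneSpec(seed=seed, noise_sd=noise_sd, noisy_bands=noisy_bands, **overrides)
    amp = separation * 2.0 * noise_sd / spec.full_scale
    fg = spec.background.with_bumps([(c, window_width_nm, amp) for c in window_centers_nm])
    return replace(spec, foreground=fg)


# ---------------------------------------------------------------------------
# Flat key=value (de)serialisation for the CLI
# ---------------------------------------------------------------------------

def _format_bumps(bumps: tuple[tuple[float, float, float], ...]) -> str:
    return ";".join(f"{c}:{w}:{a}" for c, w, a in bumps)


def _parse_bumps(text: str) -> tuple[tuple[float, float, float], ...]:
    text = text.strip()
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        c, w, a = (float(v) for v in part.split(":"))
        out.append((c, w, a))
    return tuple(out)


_SCALAR_KEYS = {
    "lines": int,
    "samples": int,
    "bands": int,
    "wavelength_min": float,
    "wavelength_max": float,
    "target_shape": str,
    "target_area_fraction": float,
    "noise_sd": float,
    "illumination_gradient": float,
    "bit_depth": int,
    "seed": int,
    "noisy_bands": int,
    "background_baseline": float,
    "background_bumps": str,
    "foreground_baseline": float,
    "foreground_bumps": str,
    # leaf-preset shortcut
    "preset": str,
    "separation": float,
    "window_centers_nm": str,
    "window_width_nm": float,
}


def scene_from_config(entries: dict[str, str]) -> SceneSpec:
    """Build a :class:`SceneSpec` from a flat key=value mapping.

    Unknown keys are rejected by name.  Either give explicit spectra
    (``background_baseline``/``background_bumps``/...) or set
    ``preset = leaf`` with ``separation``/``window_centers_nm``/
    ``window_width_nm``.
    """
    parsed: dict[str, object] = {}
    for key, raw in entries.items():
        if key not in _SCALAR_KEYS:
            raise ValueError(f"unknown scene config key '{key}'")
        parsed[key] = _SCALAR_KEYS[key](raw.strip() if isinstance(raw, str) else raw)
    kwargs: dict[str, object] = {}
    for k in (
        "lines", "samples", "bands", "target_shape", "target_area_fraction",
        "noise_sd", "illumination_gradient", "bit_depth", "seed", "noisy_bands",
    ):
        if k in parsed:
            kwargs[k] = parsed[k]
    if "wavelength_min" in parsed or "wavelength_max" in parsed:
        kwargs["wavelength_range"] = (
            float(parsed.get("wavelength_min", 400.0)),
            float(parsed.get("wavelength_max", 1000.0)),
        )
    if parsed.get("preset") == "leaf":
        centers = tuple(
            float(c) for c in str(parsed.get("window_centers_nm", "700")).split(",")
        )
        return leaf_scene(
            seed=int(kwargs.pop("seed", 0)),
            separation=float(parsed.get("separation", 5.0)),
            window_centers_nm=centers,
            window_width_nm=float(parsed.get("window_width_nm", 25.0)),
            noise_sd=float(kwargs.pop("noise_sd", 32.0)),
            noisy_bands=int(kwargs.pop("noisy_bands", 0)),
            **kwargs,
        )
    if "background_baseline" in parsed:
        kwargs["background"] = SpectrumModel(
            float(parsed["background_baseline"]),
            _parse_bumps(str(parsed.get("background_bumps", ""))),
        )
    if "foreground_baseline" in parsed:
        kwargs["foreground"] = SpectrumModel(
            float(parsed["foreground_baseline"]),
            _parse_bumps(str(parsed.get("foreground_bumps", ""))),
        )
    return SceneSpec(**kwargs)


def scene_to_config(spec: SceneSpec) -> dict[str, str]:
    """Flat key=value form of ``spec`` (inverse of :func:`scene_from_config`)."""
    return {
        "lines": str(spec.lines),
        "samples": str(spec.samples),
        "bands": str(spec.bands),
        "wavelength_min": str(spec.wavelength_range[0]),
        "wavelength_max": str(spec.wavelength_range[1]),
        "target_shape": spec.target_shape,
        "target_area_fraction": str(spec.target_area_fraction),
        "noise_sd": str(spec.noise_sd),
        "illumination_gradient": str(spec.illumination_gradient),
        "bit_depth": str(spec.bit_depth),
        "seed": str(spec.seed),
        "noisy_bands": str(spec.noisy_bands),
        "background_baseline": str(spec.background.baseline),
        "background_bumps": _format_bumps(spec.background.bumps),
        "foreground_baseline": str(spec.foreground.baseline),
        "foreground_bumps": _format_bumps(spec.foreground.bumps),
    }
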