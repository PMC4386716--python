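"""Pipeline configuration: every tunable, validated, flat-file round-trippable."""
from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig", "read_kv_file", "write_kv_file"]


@dataclass
class PipelineConfig:
    """All pipeline tunables with their defaults.

    smoothing_window
        Centred moving-average width (bands, odd) applied to the
        discriminability / loading curves before peak picking.
    min_prominence_fraction
        Peak prominence floor as a fraction of the curve maximum.
    candidate_mode
        ``local_maxima`` (all qualifying peaks) or ``global_maximum``.
    entropy_threshold_bits
        Region-entropy cut; bands above it are pruned.  1 bit is the
        entropy of the ideal equal two-region segmentation.
    connectivity
        Pixel connectivity (4 or 8) for counting spatial regions.
    pca_component
        1-based principal component whose loading curve drives the
        PCA baseline.
    """

    smoothing_window: int = 5
    min_prominence_fraction: float = 0.1
    candidate_mode: str = "local_maxima"
    entropy_threshold_bits: float = 1.0
    connectivity: int = 8
    pca_component: int = 2
    output_dir: str = "out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if not 0.0 <= self.min_prominence_fraction <= 1.0:
            raise ValueError("min_prominence_fraction must be in [0, 1]")
        if self.candidate_mode not in ("local_maxima", "global_maximum"):
            raise ValueError(f"unknown candidate_mode '{self.candidate_mode}'")
        if self.entropy_threshold_bits < 0:
            raise ValueError("entropy_threshold_bits must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.pca_component < 1:
            raise ValueError("pca_component must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        entries = read_kv_file(path)
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for key, raw in entries.items():
            if key not in known:
                raise ValueError(f"unknown config key '{key}' in {path}")
            typ = {f.name: f for f in fields(cls)}[key].type
            if typ in ("int", int):
                kwargs[key] = int(raw)
            elif typ in ("float", float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)

    def to_dict(self) -> dict[str, str]:
        return {f.name: str(getattr(self, f.name)) for f in fields(self)}

    def to_file(self, path: str | Path) -> Path:
        return write_kv_file(self.to_dict(), path)


def read_kv_file(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` file; '#' starts a comment."""
    entries: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line (expected key = value): '{line}'")
        key, _, val = line.partition("=")
        entries[key.strip()] = val.strip()
    return entries


def write_kv_file(entries: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{k} = {v}\n" for k, v in entries.items()))
    return path
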