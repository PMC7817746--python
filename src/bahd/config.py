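"""Experiment configuration for the full ranking study."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .exceptions import ParameterError
from .metrics import VOXEL, MM


@dataclass
class ExperimentConfig:
    """All knobs of the phantom ranking study.

    Defaults mirror the study scale: 10 phantoms ("patients"), 20 simulation
    sets per phantom, chains of 10 cumulative errors drawn from a 55-patch
    library, at 64^3 phantom resolution in voxel units.
    """

    n_phantoms: int = 10
    n_sets_per_phantom: int = 20
    chain_length: int = 10
    library_size: int = 55
    phantom_size: tuple[int, int, int] = (64, 64, 64)
    n_branches: int = 7
    radius_range: tuple[float, float] = (1.5, 3.0)
    units: str = VOXEL
    master_seed: int = 0
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        for name in ("n_phantoms", "n_sets_per_phantom", "chain_length", "library_size"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.chain_length > self.library_size:
            raise ParameterError(
                f"chain_length ({self.chain_length}) cannot exceed "
                f"library_size ({self.library_size})"
            )
        if self.units not in (VOXEL, MM):
            raise ParameterError(f"units must be 'voxel' or 'mm', got {self.units!r}")
        if self.output_dir is not None:
            self.output_dir = Path(self.output_dir)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "ExperimentConfig":
        """Parse a flat ``key = value`` config file; keyword overrides win."""
        values: dict = {}
        known = {f.name for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = (t.strip() for t in line.partition("="))
            if key not in known:
                raise ParameterError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _parse_value(key, val)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _parse_value(key: str, val: str):
    if key in ("phantom_size", "radius_range"):
        parts = [p for p in val.replace(",", " ").split() if p]
        nums = [float(p) for p in parts]
        return tuple(int(n) for n in nums) if key == "phantom_size" else tuple(nums)
    if key == "units":
        return val
    if key == "output_dir":
        return Path(val)
    return int(val)
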