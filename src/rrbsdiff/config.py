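"""Run configuration: defaults, validation and the flat key=value file form."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .errors import UsageError, ValidationError


@dataclass
class RunConfig:
    """All tunables of an end-to-end run.

    Defaults follow the analysis they reproduce: coverage cutoff 10 for
    testing (3 for descriptive statistics), q < 0.01, |diff| cutoff 25
    percentage points for both CpGs and tiles, at least 4 DMCs per 200-bp
    region, promoter = TSS +- 1000 bp, 2-kb CpG-island shores.
    """

    data_dir: str = "."
    outdir: str = "run"
    min_cov: int = 10
    min_cov_stats: int = 3
    q_cutoff: float = 0.01
    dmc_diff_cutoff: float = 25.0
    tile_diff_cutoff: float = 25.0
    min_dmc: int = 4
    promoter_flank: int = 1000
    shore_flank: int = 2000
    tile_width: int = 200
    hotspot_gap: int = 1000
    low_threshold: float = 10.0
    high_threshold: float = 90.0
    method: str = "logistic"
    destrand: bool = True
    seed: int = 42

    _INT = {"min_cov", "min_cov_stats", "min_dmc", "promoter_flank",
            "shore_flank", "tile_width", "hotspot_gap", "seed"}
    _FLOAT = {"q_cutoff", "dmc_diff_cutoff", "tile_diff_cutoff",
              "low_threshold", "high_threshold"}
    _BOOL = {"destrand"}

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.method not in ("fisher", "logistic"):
            raise ValidationError(f"method must be fisher or logistic, "
                                  f"got {self.method!r}")
        for name in ("min_cov", "min_cov_stats", "min_dmc", "promoter_flank",
                     "shore_flank", "tile_width", "hotspot_gap", "q_cutoff",
                     "dmc_diff_cutoff", "tile_diff_cutoff"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file (``#`` comments)."""
        kwargs = {}
        names = set(cls.field_names())
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise UsageError(f"{path}: line {i} is not key=value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in names:
                raise UsageError(f"{path}: unknown config key {key!r}")
            if key in cls._INT:
                kwargs[key] = int(value)
            elif key in cls._FLOAT:
                kwargs[key] = float(value)
            elif key in cls._BOOL:
                if value.lower() not in ("true", "false", "1", "0"):
                    raise UsageError(f"{path}: {key} must be true/false")
                kwargs[key] = value.lower() in ("true", "1")
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, bool):
                value = "true" if value else "false"
            lines.append(f"{f.name} = {value}")
        path.write_text("\n".join(lines) + "\n")
        return path
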