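"""Run configuration: paths, discounting, repetitions, seed, logging."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .simulate import DEFAULT_SEED

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration shared by the CLI subcommands.

    File paths left as ``None`` fall back to the packaged defaults (the
    1970-2009 series fixture and the default coefficient set).
    """

    series_path: str | None = None
    coefficients_path: str | None = None
    output_dir: str = "landfolio_out"
    discount_rate: float = 0.05
    horizon: int = 30
    reps: int = 1000
    seed: int = DEFAULT_SEED
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.reps < 2:
            raise ValueError("reps must be >= 2")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        for p in (self.series_path, self.coefficients_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
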