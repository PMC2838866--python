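"""Run-level configuration and the key=value config-file loader."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Union


@dataclass
class RunConfig:
    """Parameters of a sequencing run.

    ``delta`` is the relative-mass-error tolerance in Da applied when
    classifying spectrum-edge relationships; ``score_cutoff`` is the
    minimum top-tag score for a spectrum to count as sequenced;
    ``max_paths`` bounds path enumeration per component as a safeguard on
    pathological graphs.
    """

    delta: float = 0.01
    min_tag_length: int = 3
    score_cutoff: float = 4.0
    tag_mode: str = "top"  # "top" | "consensus"
    max_paths: int = 1_000_000
    residue_overrides: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.min_tag_length < 1:
            raise ValueError("min_tag_length must be >= 1")
        if self.tag_mode not in ("top", "consensus"):
            raise ValueError("tag_mode must be 'top' or 'consensus'")


def load_config(path: Union[str, Path]) -> RunConfig:
    """Read a ``key = value`` config file.

    Residue-mass overrides are written as ``mass.X = <Da>`` (e.g.
    ``mass.C = 160.03065`` for carbamidomethylated cysteine).  Lines
    starting with ``#`` are comments.
    """
    config = RunConfig()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key.startswith("mass."):
            config.residue_overrides[key[5:]] = float(value)
        elif key == "delta":
            config.delta = float(value)
        elif key == "min_tag_length":
            config.min_tag_length = int(value)
        elif key == "score_cutoff":
            config.score_cutoff = float(value)
        elif key == "tag_mode":
            config.tag_mode = value
        elif key == "max_paths":
            config.max_paths = int(value)
        else:
            raise ValueError(f"unknown config key: {key}")
    # trigger validation
    config.__post_init__()
    return config
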