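"""Run configuration: the pipeline's tunable constants in one place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .celltable import DEFAULT_PIXEL_SIZE


@dataclass
class RunConfig:
    """All pipeline constants, serializable to/from YAML losslessly.

    Defaults are the canonical run constants: 0.45 µm/pixel, neighborhood
    radii 10 and 20 µm, G_i = 20 initial mixture components, contraction
    0.8, minimum cluster size 200, family alpha 0.05.
    """

    pixel_size: float = DEFAULT_PIXEL_SIZE
    radii_um: list[float] = field(default_factory=lambda: [10.0, 20.0])
    g_initial: int = 20
    shrink_lambda: float = 0.8
    min_cluster_size: int = 200
    subclass_min_cluster_size: int | None = None
    alpha_family: float = 0.05
    alpha_marker: float = 0.05
    seed: int = 0
    n_boot: int = 1000
    junk_clusters: list[int] = field(default_factory=list)
    global_panel: list[str] | None = None
    subpanels: dict[str, list[str]] = field(default_factory=dict)
    type_col: str = "true_type"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if sorted(self.radii_um) != list(self.radii_um):
            raise ValueError("radii_um must be sorted ascending")
        if not 0.0 <= self.shrink_lambda <= 1.0:
            raise ValueError("shrink_lambda must lie in [0, 1]")

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the full configuration, for output provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
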