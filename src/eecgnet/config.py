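"""Pipeline configuration: one YAML/ dict surface validated up front."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .network import PCANetParams
from .synthetic import NoiseSpec

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, revalidated at load time.

    ``target_len`` must equal ``m * n``; network fields carry the standard
    parameter names (k1, k2, L1, L2, h1, h2, R, pad_before_blocks).
    """

    # image geometry
    m: int = 28
    n: int = 28
    # network parameters
    k1: int = 7
    k2: int = 7
    L1: int = 8
    L2: int = 8
    h1: int = 7
    h2: int = 7
    R: float = 0.5
    pad_before_blocks: bool = True
    # preprocessing
    baseline_width: int = 500
    smooth_width: int = 10
    beat_window: int = 400
    refractory: float = 0.3
    rel_threshold: float = 0.5
    # classifier
    C: float = 1.0
    # synthetic cohort
    n_subjects: int = 10
    records_per_subject: int = 6
    duration: float = 10.0
    fs: float = 500.0
    n_leads: int = 1
    noise: dict = field(default_factory=lambda: asdict(NoiseSpec()))
    # sweep grid (h, k, L, R lists)
    sweep_h: list = field(default_factory=lambda: [6])
    sweep_k: list = field(default_factory=lambda: [3, 5, 7])
    sweep_L: list = field(default_factory=lambda: [4, 8])
    sweep_R: list = field(default_factory=lambda: [0.5])
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        # raises if any Table-style constraint is violated
        self.network_params().validate_for_image(self.m, self.n)
        NoiseSpec(**self.noise)

    @property
    def target_len(self) -> int:
        return self.m * self.n

    def network_params(self) -> PCANetParams:
        return PCANetParams(
            k1=self.k1, k2=self.k2, L1=self.L1, L2=self.L2,
            h1=self.h1, h2=self.h2, R=self.R,
            pad_before_blocks=self.pad_before_blocks,
        )

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(**self.noise)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable digest of the configuration, stamped into run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file (all keys optional) and apply overrides."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            data.update(loaded)
    data.update(overrides)
    known = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
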