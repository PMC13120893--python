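"""Pipeline configuration: defaults, YAML loading, nested dataclasses."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .preprocess import PreprocessConfig
from .dfc import WindowEstimatorConfig
from .states import ClusterConfig
from .topology import TopologyConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Every numeric parameter of the analysis, with study defaults.

    Window length 70 TR with a sigma = 3 TR Gaussian taper, step 1 TR,
    per-subject cross-validated glasso penalty, L1 k-means over k = 2..10
    with 100 restarts, sparsity grid 0.10-0.34.
    """

    fd_threshold: float = 0.25
    window_length: int = 70
    gaussian_sigma: float = 3.0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    estimator: WindowEstimatorConfig = field(default_factory=WindowEstimatorConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    k_fixed: Optional[int] = None
    run_preprocess: bool = True
    run_topology: bool = True
    joint_family: bool = True
    run_group_contrasts: bool = True

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d or {})
        kwargs: dict[str, Any] = {}
        for key, sub_cls in (
            ("preprocess", PreprocessConfig),
            ("estimator", WindowEstimatorConfig),
            ("cluster", ClusterConfig),
            ("topology", TopologyConfig),
        ):
            if key in d:
                sub = d.pop(key)
                if "k_range" in sub and isinstance(sub["k_range"], list):
                    sub["k_range"] = tuple(sub["k_range"])
                kwargs[key] = sub_cls(**sub)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config, falling back to defaults for absent keys."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)
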