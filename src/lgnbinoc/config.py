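"""Pipeline configuration with YAML round-trip and deterministic seeding."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .spectral import DEFAULT_HSET


@dataclass
class PipelineConfig:
    # spike density / inclusion
    tau_g_ms: float = 1.0
    tau_d_ms: float = 20.0
    normalize_kernel: bool = True
    rate_threshold: float = 1.9          # spikes/s; strict < excludes

    # stability screening
    count_window: tuple = (-600.0, 1300.0)
    smooth_window: int = 20              # trials
    stability_penalty: float | None = None   # None -> 2*sigma^2*log(n)
    min_segment: int = 10
    stability_policy: str = "drop_outlier_segments"
    manual_overrides: dict = field(default_factory=dict)  # unit -> [[a, b), ...]

    # spectral analysis
    target_resolution_hz: float = 0.25
    hset: tuple = DEFAULT_HSET
    paired_criterion2: bool = True

    # statistics
    alpha: float = 0.05
    quantile: float = 0.975              # shuffle-null quantile for alpha=0.05
    quantile_relaxed: float = 0.9        # alpha=0.2, used for the trend count
    n_shuffles: int = 2000
    min_trials: int = 12
    mad_k: float = 3.0
    n_boot: int = 10000
    require_responsive: bool = True
    shuffle_method: str = "pooled_bootstrap"

    seed: int = 0

    def rng_for(self, stage: str, key: int = 0) -> np.random.Generator:
        """Named substream so adding units never perturbs other draws."""
        tag = int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "little")
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, tag & 0x7FFFFFFF, key]))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["count_window"] = list(self.count_window)
        d["hset"] = [float(h) for h in self.hset]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "count_window" in d:
            d["count_window"] = tuple(d["count_window"])
        if "hset" in d:
            d["hset"] = tuple(d["hset"])
        return cls(**d)
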