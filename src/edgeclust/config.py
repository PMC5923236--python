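"""Pipeline configuration with provenance-annotated defaults."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["PipelineConfig", "DEFAULT_PROVENANCE"]

#: whether each default comes from the source publication ("published") or is an
#: artifact-level choice of this implementation ("artifact")
DEFAULT_PROVENANCE = {
    "frame_interval_s": "published",
    "window_nm": "published",
    "min_distance_nm": "published",
    "min_phase_s": "published",
    "smoothing_param": "published",
    "pre_frames": "published",
    "post_frames": "published",
    "alpha_threshold": "published",
    "keep_rule": "artifact",
    "sax_M": "published",
    "sax_N": "published",
    "acf_lags": "artifact",
    "dc": "artifact",
    "k": "artifact",
    "target_neighbor_fraction": "artifact",
    "fdr_q": "artifact",
    "n_boot_ci": "published",
    "n_boot_proportion": "published",
    "seed": "artifact",
}


@dataclass
class PipelineConfig:
    frame_interval_s: float = 5.0
    window_nm: float = 500.0
    min_distance_nm: float = 720.0
    min_phase_s: float = 50.0
    smoothing_param: float = 0.01
    pre_frames: int = 5
    post_frames: int = 51
    alpha_threshold: float = 0.33
    keep_rule: str = "drop-below"
    sax_M: int = 4
    sax_N: int = 16
    acf_lags: int = 15
    dc: float | None = None  # None -> grid search
    k: int | None = None  # None -> k-scan by silhouette
    target_neighbor_fraction: float = 0.02
    fdr_q: float = 0.05
    n_boot_ci: int = 1000
    n_boot_proportion: int = 10000
    seed: int = 0

    def save(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self),
            "provenance": DEFAULT_PROVENANCE,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        data = payload["config"] if "config" in payload else payload
        return cls(**data)
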