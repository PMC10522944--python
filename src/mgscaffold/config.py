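"""Pipeline configuration: one YAML mapping, fully echoed into outputs.

A ``PipelineConfig`` bundles the phantom cohort definition (base spec
plus per-group overrides), the U-Net training settings, stitching,
morphometry and statistics options, the output directory and one global
seed from which every per-sample seed is derived. The config hash is
written into every output so report values can be traced back to the
exact settings that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .clinical_stats import GROUPS
from .morphometry import DEFAULT_CONE_HALF_ANGLE_DEG
from .segmentation import UNetSpec

# Per-group phantom overrides emulating the four treatment arms:
# thicker struts for G130, stronger degradation and more severe spots in
# the arms without drug, milder degradation under a drug-coated balloon.
DEFAULT_GROUP_OVERRIDES: dict[str, dict] = {
    "G130_10%": {
        "wall_thickness_um": 130.0,
        "strut_width_um": 130.0,
        "slight_degradation_fraction": 0.32,
        "n_severe_blobs": 3,
    },
    "G95_10%_POBA": {
        "wall_thickness_um": 95.0,
        "strut_width_um": 110.0,
        "slight_degradation_fraction": 0.45,
        "n_severe_blobs": 3,
    },
    "G95_10%_DCB": {
        "wall_thickness_um": 95.0,
        "strut_width_um": 110.0,
        "slight_degradation_fraction": 0.35,
        "n_severe_blobs": 1,
    },
    "G95_5%_DCB": {
        "wall_thickness_um": 95.0,
        "strut_width_um": 110.0,
        "slight_degradation_fraction": 0.30,
        "n_severe_blobs": 1,
    },
}

# Synthetic angiographic endpoints per arm (mean LLL mm, mean recoil %):
# non-drug arms lose more lumen and recoil more than DCB arms.
DEFAULT_LUMEN_MODEL: dict[str, dict] = {
    "G130_10%": {"lll_mean": 0.50, "recoil_mean": 10.0},
    "G95_10%_POBA": {"lll_mean": 0.45, "recoil_mean": 8.0},
    "G95_10%_DCB": {"lll_mean": 0.25, "recoil_mean": 5.0},
    "G95_5%_DCB": {"lll_mean": 0.20, "recoil_mean": 4.0},
}


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, in one structure."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    groups: dict[str, dict] = field(
        default_factory=lambda: {g: dict(DEFAULT_GROUP_OVERRIDES[g]) for g in GROUPS}
    )
    phantom_base: dict = field(default_factory=dict)  # overrides to PhantomSpec.scaled_down
    n_samples_per_group: int = 2
    n_train_volumes: int = 2  # whole-volume train/held-out split, never by patch
    n_scans: int = 2
    overlap_um: float = 120.0
    refine_overlap: bool = False
    clip_percentiles: tuple[float, float] = (0.1, 99.9)
    unet: UNetSpec = field(default_factory=UNetSpec)
    patch_size: int = 32
    patch_overlap: int = 0
    patches_per_volume: int = 120
    cone_half_angle_deg: float = DEFAULT_CONE_HALF_ANGLE_DEG
    correlation_method: str = "spearman"
    lumen_model: dict[str, dict] = field(
        default_factory=lambda: {g: dict(DEFAULT_LUMEN_MODEL[g]) for g in GROUPS}
    )
    write_volumes: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.unet, dict):
            self.unet = UNetSpec(**self.unet)
        self.clip_percentiles = tuple(self.clip_percentiles)  # type: ignore[assignment]
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")
        if not 1 <= self.n_train_volumes <= len(self.groups) * self.n_samples_per_group:
            raise ValueError("n_train_volumes out of range for the cohort size")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clip_percentiles"] = list(self.clip_percentiles)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def tiny(cls, **overrides) -> "PipelineConfig":
        """A minimal configuration for smoke runs (seconds, not minutes)."""
        base = dict(
            phantom_base=dict(
                scaffold_length_mm=0.4,
                outer_diameter_mm=0.3,
                ring_pitch_um=200.0,
                n_links=3,
                margin_um=60.0,
                severe_blob_radius_um=40.0,
            ),
            n_samples_per_group=1,
            n_train_volumes=2,
            unet=UNetSpec(base_features=4, epochs=2, batch_size=8),
            patch_size=16,
            patches_per_volume=40,
            overlap_um=80.0,
        )
        base.update(overrides)
        return cls(**base)
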