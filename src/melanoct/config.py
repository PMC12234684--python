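"""Run configuration: every threshold and kernel in one serializable object.

Defaults mirror the published operating point of the melanin pipeline:
F_RPE pixel threshold 0.15, thickened-lesion threshold 70 um, flow
threshold 0.30, attenuation normalization 10 mm^-1, 3x3 kernels. Unknown
keys are rejected on load so stale or misspelled configs fail loudly, and
every derived output is stamped with the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["SynthConfig", "RunConfig"]


@dataclass
class SynthConfig:
    patch_size: int = 64
    stride: int = 64
    overlap: float = 0.5
    split_ratio: float = 0.8
    base_channels: int = 8
    epochs: int = 6
    batch_size: int = 16
    lr: float = 2e-3
    loss: str = "bce"
    bscan_step: int = 2


@dataclass
class RunConfig:
    frpe_pixel_threshold: float = 0.15
    thickness_threshold_um: float = 70.0
    flow_threshold: float = 0.30
    mu_ref_mm1: float = 10.0
    s0_floor: float | None = None          # None -> 3x total noise power
    dopu_kernel: tuple[int, int] = (3, 3)
    angio_kernel: tuple[int, int] = (3, 3)
    atten_smooth_kernel: tuple[int, int] | None = (3, 7)
    tail_cutoff_px: int = 16
    axial_length_mm: float | None = None   # enables Littmann transverse scaling
    average_repeats_for_dopu: bool = True
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)

    # ---- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dopu_kernel"] = list(self.dopu_kernel)
        d["angio_kernel"] = list(self.angio_kernel)
        if self.atten_smooth_kernel is not None:
            d["atten_smooth_kernel"] = list(self.atten_smooth_kernel)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synth" in d and d["synth"] is not None:
            sd = dict(d["synth"])
            sknown = {f.name for f in dataclasses.fields(SynthConfig)}
            sunknown = set(sd) - sknown
            if sunknown:
                raise ValueError(f"unknown synth config keys: {sorted(sunknown)}")
            d["synth"] = SynthConfig(**sd)
        for k in ("dopu_kernel", "angio_kernel", "atten_smooth_kernel"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
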