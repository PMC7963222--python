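"""Run configuration: a strict, YAML-round-trippable description of a full
pipeline run (protocol, phantom, preprocessing, classification, seed)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .btensor import DEFAULT_N_B0, DEFAULT_SHELLS
from .phantom import LesionSpec, PhantomSpec, TissueParams, default_phantom_spec
from .preprocess import SmoothingConfig

__all__ = ["RunConfig", "ProtocolConfig", "ClassifyConfig", "PreprocessConfig"]


def _strict_kwargs(cls, d: dict[str, Any]) -> dict[str, Any]:
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return d


@dataclass(frozen=True)
class ProtocolConfig:
    shells: tuple[dict, ...] = DEFAULT_SHELLS
    n_b0: int = DEFAULT_N_B0

    def to_dict(self) -> dict:
        return {"shells": [dict(s) for s in self.shells], "n_b0": self.n_b0}

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = _strict_kwargs(cls, dict(d))
        if "shells" in d:
            d["shells"] = tuple(dict(s) for s in d["shells"])
        return cls(**d)


@dataclass(frozen=True)
class PreprocessConfig:
    sigma_factor: float = 0.42
    md_csf_threshold: float = 1.5  # um^2/ms

    def smoothing(self) -> SmoothingConfig:
        return SmoothingConfig(sigma_factor=self.sigma_factor)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**_strict_kwargs(cls, dict(d)))


@dataclass(frozen=True)
class ClassifyConfig:
    n_bins: int = 64
    contrasts: tuple[str, ...] = ("T1w", "FLAIR", "FA", "MKA")

    def to_dict(self) -> dict:
        return {"n_bins": self.n_bins, "contrasts": list(self.contrasts)}

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifyConfig":
        d = _strict_kwargs(cls, dict(d))
        if "contrasts" in d:
            d["contrasts"] = tuple(d["contrasts"])
        return cls(**d)


def _phantom_to_dict(spec: PhantomSpec) -> dict:
    return {
        "shape": list(spec.shape),
        "voxel_size": list(spec.voxel_size),
        "snr": spec.snr,
        "structural_noise_sd": spec.structural_noise_sd,
        "seed": spec.seed,
        "tissue": {k: asdict(v) for k, v in spec.tissue.items()},
        "lesions": [
            {
                "kind": l.kind,
                "center": list(l.center),
                "radius": list(l.radius),
                "wm_fraction": l.wm_fraction,
            }
            for l in spec.lesions
        ],
    }


def _phantom_from_dict(d: dict) -> PhantomSpec:
    d = _strict_kwargs(PhantomSpec, dict(d))
    kw: dict[str, Any] = {}
    if "shape" in d:
        kw["shape"] = tuple(int(x) for x in d["shape"])
    if "voxel_size" in d:
        kw["voxel_size"] = tuple(float(x) for x in d["voxel_size"])
    for key in ("snr", "structural_noise_sd"):
        if key in d:
            kw[key] = float(d[key])
    if "seed" in d:
        kw["seed"] = int(d["seed"])
    if "tissue" in d:
        kw["tissue"] = {
            k: TissueParams(**_strict_kwargs(TissueParams, dict(v)))
            for k, v in d["tissue"].items()
        }
    if "lesions" in d:
        kw["lesions"] = tuple(
            LesionSpec(
                kind=l["kind"],
                center=tuple(int(x) for x in l["center"]),
                radius=tuple(float(x) for x in l["radius"]),
                wm_fraction=float(l.get("wm_fraction", 0.0)),
            )
            for l in d["lesions"]
        )
    return PhantomSpec(**kw)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    seed: int = 0
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    phantom: PhantomSpec = field(default_factory=lambda: default_phantom_spec())
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "protocol": self.protocol.to_dict(),
            "phantom": _phantom_to_dict(self.phantom),
            "preprocess": self.preprocess.to_dict(),
            "classify": self.classify.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = _strict_kwargs(cls, dict(d))
        kw: dict[str, Any] = {}
        if "seed" in d:
            kw["seed"] = int(d["seed"])
        if "protocol" in d:
            kw["protocol"] = ProtocolConfig.from_dict(d["protocol"])
        if "phantom" in d:
            kw["phantom"] = _phantom_from_dict(d["phantom"])
        if "preprocess" in d:
            kw["preprocess"] = PreprocessConfig.from_dict(d["preprocess"])
        if "classify" in d:
            kw["classify"] = ClassifyConfig.from_dict(d["classify"])
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(d)

    def with_seed(self, seed: int) -> "RunConfig":
        from dataclasses import replace

        return replace(
            self, seed=seed, phantom=replace(self.phantom, seed=seed)
        )
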