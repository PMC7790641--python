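"""Run configuration: defaults, TOML loading, hashing."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, replace
from pathlib import Path

from .errors import ValidationError
from .synthetic import DEFAULT_TRAIT_PROBS, LandscapeConfig


@dataclass
class RunConfig:
    """Every tunable of the end-to-end pipeline, with literature defaults.

    The estimator defaults — k = 15 neighbors, a 20% training fraction and a
    25 × 25 trait-space bin grid — are the published calibration settings of
    the hypsodonty–precipitation framework and should only be changed
    deliberately.
    """

    # landscape generation
    grid_width: int = 40
    grid_height: int = 40
    n_species: int = 60
    trait_probs: tuple[float, float, float] = DEFAULT_TRAIT_PROBS
    mean_range_radius: float = 10.0
    env_intercept: float = 12.25
    env_slope: float = -3.34
    noise_sd: float = 0.3
    # community assembly
    min_richness: int = 5
    # estimators
    knn_k: int = 15
    knn_training_fraction: float = 0.2
    knn_distance_space: str = "mean_only"
    knn_holdout_only: bool = False
    ml_bins: int = 25
    ml_bin_estimate: str = "normal_mle"
    poly_degree: int = 3
    # evaluation directions
    anomaly_direction_modern: str = "observed_minus_estimated"
    anomaly_direction_paleo: str = "gcm_minus_estimated"
    # fossil sites
    n_fossil_sites: int = 43
    n_glacial: int = 31
    species_per_site: tuple[int, int] = (5, 15)
    include_out_of_space: bool = True
    n_out_of_space: int = 9
    age_match: str = "by_age_class"
    gcm_average: str = "mean_then_log"
    # randomness
    seed: int = 0

    def validate(self) -> None:
        self.landscape_config().validate()
        if self.poly_degree != 3:
            raise ValidationError(
                f"poly_degree is fixed at 3 in this framework, got {self.poly_degree}"
            )
        if not 0 < self.knn_training_fraction <= 1:
            raise ValidationError(
                f"knn_training_fraction {self.knn_training_fraction} outside (0, 1]"
            )
        if self.ml_bins < 2:
            raise ValidationError(f"ml_bins must be >= 2, got {self.ml_bins}")
        if self.knn_distance_space not in ("mean_only", "mean_sd"):
            raise ValidationError(
                f"unknown knn_distance_space '{self.knn_distance_space}'"
            )

    def landscape_config(self) -> LandscapeConfig:
        return LandscapeConfig(
            grid_width=self.grid_width,
            grid_height=self.grid_height,
            n_species=self.n_species,
            trait_probs=tuple(self.trait_probs),
            mean_range_radius=self.mean_range_radius,
            env_intercept=self.env_intercept,
            env_slope=self.env_slope,
            noise_sd=self.noise_sd,
            min_richness=self.min_richness,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trait_probs"] = list(d["trait_probs"])
        d["species_per_site"] = list(d["species_per_site"])
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys in {path}: {sorted(unknown)}")
        for key in ("trait_probs", "species_per_site"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        cfg = replace(self, **kwargs)
        cfg.validate()
        return cfg
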