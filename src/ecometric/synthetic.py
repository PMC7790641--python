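"""Synthetic landscapes, species pools, communities, and fossil sites.

The generator emulates the statistical structure the analysis assumes,
so every downstream stage is testable without external rasters or range
maps: species carry ordinal hypsodonty scores drawn from a configurable
(1, 2, 3) distribution; each species occupies a disc-shaped range on a
planar point grid, so overlapping discs produce spatially autocorrelated
communities; and log annual precipitation at each point is an affine
function of the community mean trait plus white noise,

    env_log = intercept + slope * mean_trait + Normal(0, noise_sd),

with a negative default slope (drier where communities are more
hypsodont).  With ``noise_sd = 0`` the generating line is recovered
exactly by the linear estimator, which makes parameter recovery a sharp
test.  Fossil sites are resampled whole from calibration communities
(guaranteeing in-space trait compositions) with an optional set of
constructed nonanalog sites whose (mean, SD) falls strictly outside the
calibration envelope, so the maximum-likelihood method must decline them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import (
    CommunityMetrics,
    TraitTable,
    _mean_sd,
    community_metrics,
)
from .errors import ValidationError
from .paleo import FossilSite, GCMValues

_LANDSCAPE_STREAM = 1
_FOSSIL_STREAM = 2

DEFAULT_TRAIT_PROBS = (0.3, 0.3, 0.4)


@dataclass
class LandscapeConfig:
    """Parameters of one synthetic landscape.

    Defaults give a 40×40 grid (~1,600 points) with 60 species whose mean
    range radius of 10 grid cells yields communities of roughly 5–20
    species; the generating trait–environment line defaults to the
    empirical hypsodonty–precipitation relationship (intercept 12.25 log mm,
    slope −3.34 log mm per trait unit).
    """

    grid_width: int = 40
    grid_height: int = 40
    n_species: int = 60
    trait_probs: tuple[float, float, float] = DEFAULT_TRAIT_PROBS
    mean_range_radius: float = 10.0
    env_intercept: float = 12.25
    env_slope: float = -3.34
    noise_sd: float = 0.3
    min_richness: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.grid_width < 2:
            raise ValidationError(f"grid_width must be >= 2, got {self.grid_width}")
        if self.grid_height < 2:
            raise ValidationError(f"grid_height must be >= 2, got {self.grid_height}")
        if self.min_richness < 1:
            raise ValidationError(f"min_richness must be >= 1, got {self.min_richness}")
        if self.n_species < self.min_richness:
            raise ValidationError(
                f"n_species ({self.n_species}) must be >= min_richness "
                f"({self.min_richness})"
            )
        probs = np.asarray(self.trait_probs, dtype=float)
        if probs.size != 3 or (probs < 0).any():
            raise ValidationError(f"trait_probs must be 3 nonnegative values, got {self.trait_probs}")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValidationError(f"trait_probs must sum to 1, got sum {probs.sum()!r}")
        if self.mean_range_radius <= 0:
            raise ValidationError(
                f"mean_range_radius must be > 0, got {self.mean_range_radius}"
            )
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class SyntheticLandscape:
    """A generated landscape: points, trait table, communities, environment."""

    points: pd.DataFrame  # point_id, x, y for retained points
    trait_table: TraitTable
    community_lists: dict[str, frozenset[str]]
    env_log: dict[str, float]
    truth: dict
    n_points_total: int
    n_points_filtered: int

    def validate(self) -> None:
        for pid in self.community_lists:
            if pid not in self.env_log:
                raise ValidationError(f"point '{pid}' has no env_log entry")
            if not math.isfinite(self.env_log[pid]):
                raise ValidationError(f"non-finite env_log at point '{pid}'")
            for sp in self.community_lists[pid]:
                if sp not in self.trait_table:
                    raise ValidationError(f"species '{sp}' missing from trait table")


def generate_landscape(config: LandscapeConfig) -> SyntheticLandscape:
    """Generate species ranges, communities and environment; seeded.

    Species scores come from ``trait_probs``; each range is a disc with a
    uniform-random center and a radius drawn Normal(mean_range_radius,
    mean_range_radius/4), truncated at one cell.  A point's community is
    every species whose disc covers it; points below the richness floor are
    dropped.  Environment is generated from the retained community means.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, _LANDSCAPE_STREAM])
    )
    n_sp = config.n_species
    scores = rng.choice([1, 2, 3], size=n_sp, p=np.asarray(config.trait_probs, float))
    centers = rng.uniform(
        low=[0.0, 0.0],
        high=[config.grid_width - 1.0, config.grid_height - 1.0],
        size=(n_sp, 2),
    )
    radii = np.clip(
        rng.normal(config.mean_range_radius, config.mean_range_radius / 4.0, n_sp),
        1.0,
        None,
    )
    species = [f"sp{i:03d}" for i in range(n_sp)]
    trait_table = TraitTable(dict(zip(species, (int(s) for s in scores))))

    xs, ys = np.meshgrid(
        np.arange(config.grid_width, dtype=float),
        np.arange(config.grid_height, dtype=float),
        indexing="ij",
    )
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    n_pts = pts.shape[0]
    # membership[p, s]: does species s's disc cover point p
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    membership = d2 <= (radii**2)[None, :]
    richness = membership.sum(axis=1)
    keep = richness >= config.min_richness

    sp_arr = np.array(species)
    score_arr = scores.astype(float)
    mean_trait = np.where(richness > 0, membership @ score_arr, 0.0) / np.maximum(richness, 1)

    kept_idx = np.flatnonzero(keep)
    noise = (
        rng.normal(0.0, config.noise_sd, size=kept_idx.size)
        if config.noise_sd > 0
        else np.zeros(kept_idx.size)
    )
    point_ids = [f"p{i:05d}" for i in kept_idx]
    points = pd.DataFrame(
        {"point_id": point_ids, "x": pts[kept_idx, 0], "y": pts[kept_idx, 1]}
    )
    community_lists = {
        pid: frozenset(sp_arr[membership[i]].tolist())
        for pid, i in zip(point_ids, kept_idx)
    }
    env_log = {
        pid: float(config.env_intercept + config.env_slope * mean_trait[i] + eps)
        for pid, i, eps in zip(point_ids, kept_idx, noise)
    }
    truth = {
        "env_intercept": config.env_intercept,
        "env_slope": config.env_slope,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
        "config": {
            "grid_width": config.grid_width,
            "grid_height": config.grid_height,
            "n_species": config.n_species,
            "trait_probs": list(config.trait_probs),
            "mean_range_radius": config.mean_range_radius,
            "min_richness": config.min_richness,
        },
    }
    landscape = SyntheticLandscape(
        points=points,
        trait_table=trait_table,
        community_lists=community_lists,
        env_log=env_log,
        truth=truth,
        n_points_total=int(n_pts),
        n_points_filtered=int(n_pts - kept_idx.size),
    )
    landscape.validate()
    return landscape


def landscape_metrics(landscape: SyntheticLandscape) -> list[CommunityMetrics]:
    """Community metrics of the retained landscape points (richness floor
    already applied at generation)."""
    min_r = landscape.truth["config"]["min_richness"]
    metrics, _ = community_metrics(
        landscape.community_lists, landscape.trait_table, min_richness=min_r
    )
    return metrics


def _trait_envelope(metrics: list[CommunityMetrics]) -> tuple[float, float, float, float]:
    means = np.array([m.mean for m in metrics])
    sds = np.array([m.sd for m in metrics])
    return float(means.min()), float(means.max()), float(sds.min()), float(sds.max())


def _nonanalog_compositions(
    envelope: tuple[float, float, float, float], n_species: int
) -> list[list[int]]:
    """Score compositions whose (mean, SD) is strictly outside the envelope.

    Candidates push toward the corners of achievable ordinal trait space:
    uniform communities (SD 0 at mean 1, 2 or 3) and balanced 1/3 mixtures
    (maximal SD).  Only candidates strictly outside the calibration
    envelope are returned, so a downstream maximum-likelihood query is
    missing regardless of bin count.
    """
    lo_m, hi_m, lo_s, hi_s = envelope
    n = max(6, n_species)
    half = n // 2
    candidates = [
        [1] * n,
        [3] * n,
        [2] * n,
        [1] * half + [3] * (n - half),
        [1] * (n - 2) + [3] * 2,
        [3] * (n - 2) + [1] * 2,
    ]
    passing = []
    for comp in candidates:
        mean, sd = _mean_sd(np.array(comp, dtype=float))
        if mean < lo_m or mean > hi_m or sd < lo_s or sd > hi_s:
            passing.append(comp)
    return passing


def generate_fossil_sites(
    landscape: SyntheticLandscape,
    n_sites: int = 43,
    n_glacial: int = 31,
    species_per_site: tuple[int, int] = (5, 15),
    include_out_of_space: bool = True,
    seed: int = 0,
    n_out_of_space: int = 9,
    gcm_mismatch_offset: float = -0.4,
    gcm_model_half_spread: float = 0.15,
    gcm_noise_sd: float = 0.05,
) -> tuple[list[FossilSite], list[GCMValues]]:
    """Synthetic fossil communities with glacial/interglacial GCM values.

    In-space sites copy whole communities from randomly chosen calibration
    points whose richness lies within ``species_per_site``; nonanalog sites
    (when ``include_out_of_space``) use constructed compositions strictly
    outside the calibration (mean, SD) envelope.  GCM precipitation is
    generated from the landscape truth: the model matching a site's own age
    class sits at the true value (small model spread and noise) while the
    opposite class carries ``gcm_mismatch_offset`` log mm, so age-matched
    comparisons are closer by construction.
    """
    lo_sp, hi_sp = int(species_per_site[0]), int(species_per_site[1])
    if lo_sp < 5:
        raise ValidationError(
            f"species_per_site minimum must be >= 5 (inclusion floor), got {lo_sp}"
        )
    if hi_sp < lo_sp:
        raise ValidationError(f"species_per_site range {species_per_site} is empty")
    if n_glacial > n_sites:
        raise ValidationError(f"n_glacial ({n_glacial}) exceeds n_sites ({n_sites})")
    n_out = int(n_out_of_space) if include_out_of_space else 0
    if n_out > n_sites:
        raise ValidationError(f"n_out_of_space ({n_out}) exceeds n_sites ({n_sites})")

    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _FOSSIL_STREAM])
    )
    metrics = landscape_metrics(landscape)
    by_id = {m.point_id: m for m in metrics}
    envelope = _trait_envelope(metrics)
    eligible = [m.point_id for m in metrics if lo_sp <= m.richness <= hi_sp]
    n_in = n_sites - n_out
    if not eligible and n_in > 0:
        raise ValidationError(
            f"no calibration community has richness within {species_per_site}"
        )
    chosen = rng.choice(
        np.array(eligible), size=n_in, replace=len(eligible) < n_in
    ) if n_in > 0 else np.array([], dtype=str)

    comps = _nonanalog_compositions(envelope, lo_sp + 1)
    if n_out > 0 and not comps:
        raise ValidationError(
            "could not construct a trait composition outside the calibration "
            "envelope; widen the landscape or lower n_out_of_space"
        )

    point_xy = landscape.points.set_index("point_id")
    intercept = landscape.truth["env_intercept"]
    slope = landscape.truth["env_slope"]

    sites: list[FossilSite] = []
    for i, pid in enumerate(chosen):
        comm = sorted(landscape.community_lists[str(pid)])
        occ = tuple((sp, landscape.trait_table.score(sp)) for sp in comm)
        sites.append(
            FossilSite(
                site_id=f"fs{i:03d}",
                x=float(point_xy.loc[str(pid), "x"]),
                y=float(point_xy.loc[str(pid), "y"]),
                age_class="glacial",  # reassigned below
                occurrences=occ,
            )
        )
    for j in range(n_out):
        comp = comps[j % len(comps)]
        occ = tuple((f"fossil_taxon_{j:02d}_{k:02d}", int(s)) for k, s in enumerate(comp))
        sites.append(
            FossilSite(
                site_id=f"fs{n_in + j:03d}",
                x=float(rng.uniform(0, landscape.truth["config"]["grid_width"] - 1)),
                y=float(rng.uniform(0, landscape.truth["config"]["grid_height"] - 1)),
                age_class="glacial",
                occurrences=occ,
            )
        )

    ages = np.array(["interglacial"] * n_sites, dtype=object)
    ages[rng.permutation(n_sites)[:n_glacial]] = "glacial"
    sites = [
        FossilSite(s.site_id, s.x, s.y, str(age), s.occurrences)
        for s, age in zip(sites, ages)
    ]

    gcms: list[GCMValues] = []
    d = gcm_model_half_spread
    for site in sites:
        scores = np.array([sc for _, sc in site.occurrences], dtype=float)
        mean, _ = _mean_sd(scores)
        mu = intercept + slope * mean
        eps = rng.normal(0.0, gcm_noise_sd, size=3) if gcm_noise_sd > 0 else np.zeros(3)
        if site.age_class == "glacial":
            g1 = math.exp(mu - d + eps[0])
            g2 = math.exp(mu + d + eps[1])
            inter = math.exp(mu + gcm_mismatch_offset + eps[2])
        else:
            g1 = math.exp(mu + gcm_mismatch_offset - d + eps[0])
            g2 = math.exp(mu + gcm_mismatch_offset + d + eps[1])
            inter = math.exp(mu + eps[2])
        gcms.append(
            GCMValues(
                site_id=site.site_id,
                glacial_model_values=(g1, g2),
                interglacial_value=inter,
            )
        )
    return sites, gcms
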