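"""Application of fitted estimators to Late Pleistocene fossil communities.

Fossil sites carry their own per-taxon hypsodonty scores (fossil taxa need
not appear in the modern trait table).  Site metrics use one occurrence per
species — duplicates are collapsed before the mean/SD so a repeatedly
collected taxon is not double-weighted — and sites keep the same
five-species inclusion floor as the modern calibration.  Each site receives
four precipitation estimates; the binned maximum-likelihood method may
decline sites whose trait composition falls outside the modern calibration
space, and those refusals are counted by age class.  Estimates are compared
with climate-model (GCM) precipitation: the reference for a glacial site is
the mean of the two glacial model values (CCSM4-like and MIROC-like,
averaged on the mm scale by default) and for an interglacial site the
single interglacial value; anomalies are GCM minus estimate on the natural
log scale — the reverse of the modern-evaluation direction.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import CommunityMetrics, VALID_SCORES, _mean_sd, normalize_species_name
from .errors import ValidationError
from .estimators import ModelSet, predict_knn, predict_linear, predict_mlgrid, predict_polynomial

AGE_CLASSES = ("glacial", "interglacial")

MIN_FOSSIL_SPECIES = 5

METHODS = ("linear", "polynomial", "knn", "mlgrid")


@dataclass(frozen=True)
class FossilSite:
    """One fossil locality: coordinates, age class, scored occurrences.

    ``occurrences`` is a sequence of (species, score) pairs and may contain
    repeats of the same taxon, as collection records do.
    """

    site_id: str
    x: float
    y: float
    age_class: str
    occurrences: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(
                f"site '{self.site_id}': age_class '{self.age_class}' "
                f"not in {AGE_CLASSES}"
            )
        for sp, score in self.occurrences:
            if int(score) not in VALID_SCORES:
                raise ValidationError(
                    f"site '{self.site_id}': score {score} for '{sp}' outside {{1, 2, 3}}"
                )


def dedupe_occurrences(site: FossilSite) -> dict[str, int]:
    """Collapse repeated taxa to one occurrence; conflicting scores are an error."""
    seen: dict[str, int] = {}
    for sp, score in site.occurrences:
        key = normalize_species_name(sp).casefold()
        score = int(score)
        if key in seen and seen[key] != score:
            raise ValidationError(
                f"site '{site.site_id}': conflicting scores for species '{sp}'"
            )
        seen[key] = score
    return seen


def fossil_metrics(site: FossilSite, min_species: int = MIN_FOSSIL_SPECIES) -> CommunityMetrics:
    """Trait mean/SD of a fossil site over one occurrence per species."""
    scores = np.array(sorted(dedupe_occurrences(site).values()), dtype=float)
    if scores.size < min_species:
        raise ValidationError(
            f"site '{site.site_id}' has {scores.size} distinct species "
            f"(inclusion floor is {min_species})"
        )
    mean, sd = _mean_sd(scores)
    return CommunityMetrics(point_id=site.site_id, mean=mean, sd=sd, richness=scores.size)


def estimate_paleo(
    sites: Sequence[FossilSite], models: ModelSet
) -> tuple[pd.DataFrame, dict]:
    """Four precipitation estimates per fossil site.

    Returns an estimates table (NaN where the maximum-likelihood grid has no
    occupied bin for the site) and a coverage report of ML-missing counts and
    fractions by age class.
    """
    rows = []
    for site in sites:
        m = fossil_metrics(site)
        rows.append(
            {
                "site_id": site.site_id,
                "x": site.x,
                "y": site.y,
                "age_class": site.age_class,
                "mean": m.mean,
                "sd": m.sd,
                "richness": m.richness,
                "linear": predict_linear(models.linear, m.mean),
                "polynomial": predict_polynomial(models.polynomial, m.mean),
                "knn": predict_knn(
                    models.knn, m.mean,
                    m.sd if models.knn.distance_space == "mean_sd" else None,
                ),
                "mlgrid": predict_mlgrid(models.mlgrid, m.mean, m.sd),
            }
        )
    table = pd.DataFrame(rows)
    coverage: dict = {"by_age_class": {}, "n_sites": len(table)}
    missing_total = 0
    for age in AGE_CLASSES:
        sub = table[table["age_class"] == age]
        n_missing = int(sub["mlgrid"].isna().sum())
        missing_total += n_missing
        coverage["by_age_class"][age] = {
            "n_sites": int(len(sub)),
            "ml_missing": n_missing,
            "ml_missing_fraction": (n_missing / len(sub)) if len(sub) else 0.0,
        }
    coverage["ml_missing"] = missing_total
    coverage["ml_missing_fraction"] = (
        missing_total / len(table) if len(table) else 0.0
    )
    return table, coverage


@dataclass(frozen=True)
class GCMValues:
    """Climate-model precipitation (mm) for one fossil site."""

    site_id: str
    glacial_model_values: tuple[float, float]
    interglacial_value: float

    def __post_init__(self) -> None:
        for v in (*self.glacial_model_values, self.interglacial_value):
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"site '{self.site_id}': GCM precipitation {v!r} must be > 0 mm"
                )


def _reference_log(gcm: GCMValues, age: str, average: str) -> float:
    if age == "glacial":
        a, b = gcm.glacial_model_values
        if average == "mean_then_log":
            return math.log((a + b) / 2.0)
        if average == "log_then_mean":
            return (math.log(a) + math.log(b)) / 2.0
        raise ValidationError(f"unknown GCM averaging mode '{average}'")
    return math.log(gcm.interglacial_value)


def compare_to_gcm(
    estimates: pd.DataFrame,
    gcm: Iterable[GCMValues],
    age_match: str = "by_age_class",
    gcm_average: str = "mean_then_log",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Anomalies of climate-model minus estimated log precipitation per site.

    ``age_match`` selects the reference: ``by_age_class`` uses each site's
    own age class; ``force_glacial`` / ``force_interglacial`` compare every
    site against that class's models (the cross-comparison used to ask
    whether interglacial faunas look glacial).  Returns a long anomaly table
    and a summary split by age class and method with ML-missing counted.
    """
    if age_match not in ("by_age_class", "force_glacial", "force_interglacial"):
        raise ValidationError(f"unknown age_match '{age_match}'")
    by_site = {g.site_id: g for g in gcm}
    rows = []
    for _, site in estimates.iterrows():
        sid = str(site["site_id"])
        if sid not in by_site:
            raise ValidationError(f"no GCM values for site '{sid}'")
        age = site["age_class"]
        ref_age = {"by_age_class": age,
                   "force_glacial": "glacial",
                   "force_interglacial": "interglacial"}[age_match]
        ref_log = _reference_log(by_site[sid], ref_age, gcm_average)
        for method in METHODS:
            est = float(site[method])
            rows.append(
                {
                    "site_id": sid,
                    "age_class": age,
                    "reference_age": ref_age,
                    "method": method,
                    "reference_log_mm": ref_log,
                    "estimate_log_mm": est,
                    "anomaly_log_mm": ref_log - est,  # GCM minus estimate
                }
            )
    anomalies = pd.DataFrame(rows)
    summaries = []
    for (age, method), sub in anomalies.groupby(["age_class", "method"], sort=True):
        v = sub["anomaly_log_mm"].dropna()
        summaries.append(
            {
                "age_class": age,
                "method": method,
                "n": int(len(v)),
                "n_missing": int(sub["anomaly_log_mm"].isna().sum()),
                "mean": float(v.mean()) if len(v) else float("nan"),
                "median": float(v.median()) if len(v) else float("nan"),
                "min": float(v.min()) if len(v) else float("nan"),
                "max": float(v.max()) if len(v) else float("nan"),
            }
        )
    return anomalies, pd.DataFrame(summaries)
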