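"""Community trait metrics and calibration assembly.

A community is the set of species whose geographic ranges cover a sampling
point.  Each species carries an ordinal hypsodonty score — 1 (brachydont,
low molar crown), 2 (mesodont) or 3 (hypsodont, high crown; ever-growing
hypselodont dentition is scored 3).  The community-level summaries used
throughout are the arithmetic mean and the sample standard deviation
(n−1 denominator) of the member scores, computed over scored occurrences
(one per species).  Points with fewer than ``min_richness`` scored species
are excluded, and the environmental variable — annual precipitation in mm —
is paired with each retained community on the natural-log scale.
"""

from __future__ import annotations

import math
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .reporting import FilterReport

VALID_SCORES = frozenset({1, 2, 3})

DEFAULT_MIN_RICHNESS = 5

_WS = re.compile(r"\s+")


def normalize_species_name(name: str) -> str:
    """Strip and collapse internal whitespace; case is preserved."""
    return _WS.sub(" ", str(name).strip())


class TraitTable:
    """Mapping from species name to ordinal hypsodonty score in {1, 2, 3}.

    Names are whitespace-normalized; duplicate entries that agree are
    collapsed silently, while case-insensitive duplicates with conflicting
    scores are rejected at construction.
    """

    def __init__(self, scores: Mapping[str, int]):
        self._scores: dict[str, int] = {}
        self._by_fold: dict[str, str] = {}
        conflicts: list[str] = []
        for raw_name, raw_score in scores.items():
            name = normalize_species_name(raw_name)
            self._add(name, raw_score, conflicts)
        if conflicts:
            raise ValidationError(
                "conflicting trait scores for species: " + ", ".join(sorted(set(conflicts)))
            )

    def _add(self, name: str, raw_score, conflicts: list[str]) -> None:
        if not name:
            raise ValidationError("empty species name in trait table")
        try:
            score = int(raw_score)
            if score != float(raw_score):
                raise ValueError
        except (TypeError, ValueError):
            raise ValidationError(
                f"non-integer trait score {raw_score!r} for species '{name}'"
            ) from None
        if score not in VALID_SCORES:
            raise ValidationError(
                f"trait score {score} for species '{name}' outside {{1, 2, 3}}"
            )
        fold = name.casefold()
        if fold in self._by_fold:
            canonical = self._by_fold[fold]
            if self._scores[canonical] != score:
                conflicts.append(canonical)
            return
        self._by_fold[fold] = name
        self._scores[name] = score

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, int]]) -> "TraitTable":
        table = cls({})
        conflicts: list[str] = []
        for raw_name, raw_score in rows:
            table._add(normalize_species_name(raw_name), raw_score, conflicts)
        if conflicts:
            raise ValidationError(
                "conflicting trait scores for species: " + ", ".join(sorted(set(conflicts)))
            )
        if not table._scores:
            raise ValidationError("trait table is empty")
        return table

    def score(self, species: str) -> int:
        fold = normalize_species_name(species).casefold()
        try:
            return self._scores[self._by_fold[fold]]
        except KeyError:
            raise ValidationError(f"species '{species}' not in trait table") from None

    def __contains__(self, species: str) -> bool:
        return normalize_species_name(species).casefold() in self._by_fold

    def __len__(self) -> int:
        return len(self._scores)

    @property
    def species(self) -> list[str]:
        return list(self._scores)

    def items(self):
        return self._scores.items()


def load_and_validate_traits(rows) -> TraitTable:
    """Build a :class:`TraitTable` from raw (species, score) rows.

    ``rows`` may be an iterable of pairs or a DataFrame with columns
    ``species`` and ``score``.  Idempotent duplicates collapse; conflicting
    duplicates raise naming every species involved.
    """
    if isinstance(rows, pd.DataFrame):
        missing = {"species", "score"} - set(rows.columns)
        if missing:
            raise ValidationError(f"trait table missing columns: {sorted(missing)}")
        rows = list(zip(rows["species"], rows["score"]))
    else:
        rows = list(rows)
    if not rows:
        raise ValidationError("trait table is empty")
    return TraitTable.from_rows(rows)


@dataclass(frozen=True)
class CommunityMetrics:
    """Trait mean/SD and richness of one community (sampling point or site)."""

    point_id: str
    mean: float
    sd: float
    richness: int


def _mean_sd(scores: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1)) if scores.size > 1 else 0.0
    return mean, sd


def community_metrics(
    community_lists: Mapping[str, Iterable[str]],
    traits: TraitTable,
    min_richness: int = DEFAULT_MIN_RICHNESS,
) -> tuple[list[CommunityMetrics], FilterReport]:
    """Compute per-point trait mean/SD, applying the richness floor.

    A species missing from the trait table is a hard error (a silent drop
    would bias the community mean invisibly).  Points whose scored richness
    falls below ``min_richness`` are excluded and counted in the returned
    :class:`FilterReport`.
    """
    report = FilterReport(stage="richness_filter", n_in=len(community_lists))
    out: list[CommunityMetrics] = []
    for point_id, members in community_lists.items():
        members = list(members)
        scores = np.empty(len(members))
        for i, sp in enumerate(members):
            try:
                scores[i] = traits.score(sp)
            except ValidationError:
                raise ValidationError(
                    f"species '{sp}' at point '{point_id}' not in trait table"
                ) from None
        if len(members) != len({normalize_species_name(m).casefold() for m in members}):
            raise ValidationError(f"duplicate species in community at point '{point_id}'")
        if scores.size < min_richness:
            report.drop(f"richness < {min_richness}")
            continue
        mean, sd = _mean_sd(scores)
        out.append(CommunityMetrics(str(point_id), mean, sd, scores.size))
    report.n_out = len(out)
    report.validate()
    return out, report


@dataclass
class CalibrationSet:
    """Paired community metrics and log-precipitation observations.

    ``records`` has one row per point with columns
    ``point_id, mean, sd, richness, env_log``; ``env_log`` is natural-log
    precipitation in log mm (transform tag ``ln_mm``).
    """

    records: pd.DataFrame
    transform: str = "ln_mm"

    def __post_init__(self) -> None:
        required = {"point_id", "mean", "sd", "richness", "env_log"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValidationError(f"calibration records missing columns: {sorted(missing)}")
        dup = self.records["point_id"].duplicated()
        if dup.any():
            raise ValidationError(
                "duplicate point_id in calibration set: "
                + ", ".join(map(str, self.records.loc[dup, "point_id"].head(5)))
            )
        if not np.isfinite(self.records["env_log"].to_numpy(float)).all():
            raise ValidationError("non-finite env_log in calibration set")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def means(self) -> np.ndarray:
        return self.records["mean"].to_numpy(float)

    @property
    def sds(self) -> np.ndarray:
        return self.records["sd"].to_numpy(float)

    @property
    def env_log(self) -> np.ndarray:
        return self.records["env_log"].to_numpy(float)

    @property
    def point_ids(self) -> list[str]:
        return self.records["point_id"].astype(str).tolist()


def build_calibration(
    metrics: Iterable[CommunityMetrics],
    env: Mapping[str, float],
) -> CalibrationSet:
    """Pair community metrics with natural-log precipitation.

    ``env`` maps point_id to annual precipitation in mm; values must be
    present and strictly positive for every retained point (no imputation).
    """
    rows = []
    for m in metrics:
        if m.point_id not in env:
            raise ValidationError(f"no precipitation value for point '{m.point_id}'")
        precip = float(env[m.point_id])
        if not math.isfinite(precip) or precip <= 0:
            raise ValidationError(
                f"precipitation {precip!r} at point '{m.point_id}' is not a positive number"
            )
        rows.append((m.point_id, m.mean, m.sd, m.richness, math.log(precip)))
    if not rows:
        raise ValidationError("calibration set would be empty")
    records = pd.DataFrame(rows, columns=["point_id", "mean", "sd", "richness", "env_log"])
    return CalibrationSet(records=records)


def calibration_from_log(
    metrics: Iterable[CommunityMetrics], env_log: Mapping[str, float]
) -> CalibrationSet:
    """Build a calibration set from already log-transformed values.

    Used by the synthetic generator, whose truth is defined on the log scale;
    avoids an exp/log round trip in exactness tests.
    """
    rows = []
    for m in metrics:
        if m.point_id not in env_log:
            raise ValidationError(f"no environment value for point '{m.point_id}'")
        rows.append((m.point_id, m.mean, m.sd, m.richness, float(env_log[m.point_id])))
    if not rows:
        raise ValidationError("calibration set would be empty")
    records = pd.DataFrame(rows, columns=["point_id", "mean", "sd", "richness", "env_log"])
    return CalibrationSet(records=records)
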