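"""Four trait→environment inference methods behind one fit/predict contract.

All four map community hypsodonty metrics to log annual precipitation
(log mm), calibrated on modern communities:

* ordinary least-squares **linear** regression of log precipitation on the
  community trait mean;
* degree-3 **polynomial** regression on the trait mean (fit on a
  domain-scaled basis for conditioning, coefficients reported in the raw
  power basis);
* **k-nearest-neighbor** regression: a seeded random training subset is
  stored and a query is answered by the unweighted mean of its k closest
  training communities (k = 15, 20% training fraction by default);
* **maximum-likelihood trait-space binning**: calibration communities are
  binned on a 25 × 25 grid over (trait mean, trait SD) and each occupied
  bin stores the most likely precipitation value for that trait
  composition — under the default normal model of member values, their
  mean.

The binning method is the only one that can decline to answer: a query
outside the occupied bins (a nonanalog community) yields NaN, a value, not
an exception, because out-of-space fossil communities are an expected
outcome that downstream summaries must count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P
from scipy import stats

from .communities import CalibrationSet
from .errors import ValidationError

MISSING = float("nan")

DEFAULT_K = 15
DEFAULT_TRAINING_FRACTION = 0.2
DEFAULT_N_BINS = 25

_KNN_STREAM = 4


def _require_finite(value, what: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"non-finite {what}: {value!r}")
    return arr


# ---------------------------------------------------------------------------
# linear regression


@dataclass
class LinearModel:
    intercept: float
    slope: float
    r_squared: float
    n: int
    slope_stderr: float
    fitted_range: tuple[float, float]

    def predict(self, mean):
        return predict_linear(self, mean)

    def in_fitted_range(self, mean) -> np.ndarray:
        m = np.asarray(mean, dtype=float)
        lo, hi = self.fitted_range
        return (m >= lo) & (m <= hi)


def fit_linear(cal: CalibrationSet) -> LinearModel:
    """OLS of log precipitation on community trait mean, with intercept."""
    x, y = cal.means, cal.env_log
    if x.size < 3:
        raise ValidationError(f"linear fit needs >= 3 records, got {x.size}")
    if np.ptp(x) == 0:
        raise ValidationError("constant trait means: linear slope undefined")
    res = stats.linregress(x, y)
    return LinearModel(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
        slope_stderr=float(res.stderr),
        fitted_range=(float(x.min()), float(x.max())),
    )


def predict_linear(model: LinearModel, mean):
    m = _require_finite(mean, "trait mean")
    out = model.intercept + model.slope * m
    return float(out) if np.isscalar(mean) or m.ndim == 0 else out


# ---------------------------------------------------------------------------
# cubic polynomial regression


@dataclass
class PolyModel:
    degree: int
    coefficients: tuple[float, float, float, float]  # raw power basis, ascending
    basis: str
    scaled_coefficients: tuple[float, ...]  # coefficients on the scaled domain
    domain: tuple[float, float]
    r_squared: float
    n: int
    fitted_range: tuple[float, float]
    min_prediction: float  # smallest value the curve attains on fitted_range
    argmin_mean: float

    def predict(self, mean):
        return predict_polynomial(self, mean)

    def in_fitted_range(self, mean) -> np.ndarray:
        m = np.asarray(mean, dtype=float)
        lo, hi = self.fitted_range
        return (m >= lo) & (m <= hi)


def _poly_minimum(coef: np.ndarray, lo: float, hi: float) -> tuple[float, float]:
    """Exact minimum of a cubic on [lo, hi]: endpoints + real critical points."""
    candidates = [lo, hi]
    deriv = P.polyder(coef)
    for r in P.polyroots(deriv):
        if abs(r.imag) < 1e-12 and lo <= r.real <= hi:
            candidates.append(float(r.real))
    values = P.polyval(np.array(candidates), coef)
    i = int(np.argmin(values))
    return float(candidates[i]), float(values[i])


def fit_polynomial(cal: CalibrationSet) -> PolyModel:
    """Degree-3 least squares of log precipitation on trait mean.

    The fit runs on numpy's scaled domain (means mapped to [-1, 1]) and the
    coefficients are converted back to the raw power basis for reporting.
    The curve's minimum over the fitted range is recorded because the cubic's
    shape imposes a floor on predictable precipitation.
    """
    x, y = cal.means, cal.env_log
    if x.size < 5:
        raise ValidationError(f"polynomial fit needs >= 5 records, got {x.size}")
    if np.ptp(x) == 0:
        raise ValidationError("constant trait means: polynomial fit undefined")
    fitted = np.polynomial.Polynomial.fit(x, y, deg=3)
    raw = fitted.convert().coef
    raw = np.pad(raw, (0, 4 - raw.size))  # trailing near-zero terms may be trimmed
    pred = P.polyval(x, raw)
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    lo, hi = float(x.min()), float(x.max())
    argmin_mean, min_pred = _poly_minimum(raw, lo, hi)
    return PolyModel(
        degree=3,
        coefficients=tuple(float(c) for c in raw),
        basis="raw",
        scaled_coefficients=tuple(float(c) for c in fitted.coef),
        domain=(float(fitted.domain[0]), float(fitted.domain[1])),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n=int(x.size),
        fitted_range=(lo, hi),
        min_prediction=min_pred,
        argmin_mean=argmin_mean,
    )


def predict_polynomial(model: PolyModel, mean):
    m = _require_finite(mean, "trait mean")
    out = P.polyval(m, np.asarray(model.coefficients))
    return float(out) if np.isscalar(mean) or m.ndim == 0 else out


# ---------------------------------------------------------------------------
# k-nearest-neighbor regression


@dataclass
class KNNModel:
    k: int
    training_fraction: float
    distance_space: str  # "mean_only" or "mean_sd"
    seed: int
    train_means: np.ndarray
    train_sds: np.ndarray
    train_env: np.ndarray
    train_point_ids: tuple[str, ...]

    @property
    def n_train(self) -> int:
        return int(self.train_means.size)

    def predict(self, mean, sd=None):
        return predict_knn(self, mean, sd)


def fit_knn(
    cal: CalibrationSet,
    k: int = DEFAULT_K,
    training_fraction: float = DEFAULT_TRAINING_FRACTION,
    distance_space: str = "mean_only",
    seed: int = 0,
) -> KNNModel:
    """Store a seeded random training subset for nearest-neighbor lookup.

    ``round(training_fraction * n)`` records are drawn uniformly without
    replacement.  The default 20% training fraction follows the calibration
    convention of the hypsodonty literature rather than the more common 80%.
    """
    if not 0 < training_fraction <= 1:
        raise ValidationError(f"training_fraction {training_fraction} outside (0, 1]")
    if distance_space not in ("mean_only", "mean_sd"):
        raise ValidationError(f"unknown distance_space '{distance_space}'")
    n = cal.n
    n_train = n if training_fraction == 1.0 else int(round(training_fraction * n))
    if k > n_train:
        raise ValidationError(f"k={k} exceeds training size {n_train}")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _KNN_STREAM]))
    idx = rng.choice(n, size=n_train, replace=False)
    ids = cal.point_ids
    return KNNModel(
        k=int(k),
        training_fraction=float(training_fraction),
        distance_space=distance_space,
        seed=int(seed),
        train_means=cal.means[idx].copy(),
        train_sds=cal.sds[idx].copy(),
        train_env=cal.env_log[idx].copy(),
        train_point_ids=tuple(ids[i] for i in idx),
    )


def _knn_one(model: KNNModel, mean: float, sd: Optional[float]) -> float:
    if model.distance_space == "mean_sd":
        d2 = (model.train_means - mean) ** 2 + (model.train_sds - sd) ** 2
    else:
        d2 = (model.train_means - mean) ** 2
    # stable argsort: ties at the k-th distance resolve by training index
    order = np.argsort(d2, kind="stable")
    return float(model.train_env[order[: model.k]].mean())


def predict_knn(model: KNNModel, mean, sd=None):
    """Unweighted mean of the k nearest training records (Euclidean distance).

    ``sd`` is required iff the model was fit with ``distance_space='mean_sd'``.
    """
    if model.distance_space == "mean_sd":
        if sd is None:
            raise ValidationError("distance_space 'mean_sd' requires a query sd")
        s = _require_finite(sd, "trait sd")
    else:
        s = None
    m = _require_finite(mean, "trait mean")
    if m.ndim == 0:
        return _knn_one(model, float(m), None if s is None else float(s))
    s_arr = np.broadcast_to(s, m.shape) if s is not None else [None] * m.size
    return np.array(
        [_knn_one(model, float(mi), None if si is None else float(si))
         for mi, si in zip(m, s_arr)]
    )


# ---------------------------------------------------------------------------
# maximum-likelihood trait-space binning


@dataclass
class MLGridModel:
    n_bins: int
    mean_edges: np.ndarray  # n_bins + 1 ascending values
    sd_edges: np.ndarray
    bin_estimates: np.ndarray  # (n_bins, n_bins), NaN where unoccupied
    bin_counts: np.ndarray  # (n_bins, n_bins) ints
    bin_estimate: str  # "normal_mle" or "hist_mode"

    @property
    def envelope(self) -> tuple[float, float, float, float]:
        """(min mean, max mean, min sd, max sd) of the calibration space."""
        return (
            float(self.mean_edges[0]),
            float(self.mean_edges[-1]),
            float(self.sd_edges[0]),
            float(self.sd_edges[-1]),
        )

    def predict(self, mean, sd):
        return predict_mlgrid(self, mean, sd)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins [lo, hi); the last bin is closed so the max lands in it."""
    n_bins = edges.size - 1
    lo, hi = edges[0], edges[-1]
    idx = np.floor((values - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _hist_mode(values: np.ndarray, n_hist: int = 10) -> float:
    if np.ptp(values) == 0:
        return float(values[0])
    counts, edges = np.histogram(values, bins=n_hist)
    i = int(np.argmax(counts))  # ties resolve to the lowest bin
    return float(0.5 * (edges[i] + edges[i + 1]))


def fit_mlgrid(
    cal: CalibrationSet,
    n_bins: int = DEFAULT_N_BINS,
    bin_estimate: str = "normal_mle",
) -> MLGridModel:
    """Bin calibration communities on an equal-width (mean, SD) grid.

    Each occupied bin stores the most likely precipitation value for
    communities of that trait composition: under the default normal model of
    member log-precipitation values this is their mean; ``hist_mode`` instead
    takes the center of the fullest cell of a 10-bin histogram.
    """
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    if bin_estimate not in ("normal_mle", "hist_mode"):
        raise ValidationError(f"unknown bin_estimate '{bin_estimate}'")
    if cal.n < 1:
        raise ValidationError("empty calibration set")
    means, sds, env = cal.means, cal.sds, cal.env_log
    if np.ptp(means) == 0 or np.ptp(sds) == 0:
        raise ValidationError(
            "calibration means or SDs are constant: cannot span a 2-D bin grid"
        )
    mean_edges = np.linspace(means.min(), means.max(), n_bins + 1)
    sd_edges = np.linspace(sds.min(), sds.max(), n_bins + 1)
    mi = _bin_index(means, mean_edges)
    si = _bin_index(sds, sd_edges)
    counts = np.zeros((n_bins, n_bins), dtype=int)
    np.add.at(counts, (mi, si), 1)
    estimates = np.full((n_bins, n_bins), np.nan)
    groups = pd.DataFrame({"i": mi, "j": si, "y": env}).groupby(["i", "j"])["y"]
    for (i, j), values in groups:
        arr = values.to_numpy()
        estimates[i, j] = arr.mean() if bin_estimate == "normal_mle" else _hist_mode(arr)
    return MLGridModel(
        n_bins=int(n_bins),
        mean_edges=mean_edges,
        sd_edges=sd_edges,
        bin_estimates=estimates,
        bin_counts=counts,
        bin_estimate=bin_estimate,
    )


def predict_mlgrid(model: MLGridModel, mean, sd):
    """Estimate of the bin containing (mean, sd); NaN outside occupied space.

    NaN — not an exception — because nonanalog queries are an expected,
    counted outcome when fossil communities are pushed through a modern
    calibration.
    """
    m = _require_finite(mean, "trait mean")
    s = _require_finite(sd, "trait sd")
    m, s = np.broadcast_arrays(m, s)
    scalar = m.ndim == 0
    m = np.atleast_1d(m).astype(float)
    s = np.atleast_1d(s).astype(float)
    lo_m, hi_m, lo_s, hi_s = model.envelope
    out = np.full(m.shape, np.nan)
    inside = (m >= lo_m) & (m <= hi_m) & (s >= lo_s) & (s <= hi_s)
    if inside.any():
        mi = _bin_index(m[inside], model.mean_edges)
        si = _bin_index(s[inside], model.sd_edges)
        out[inside] = model.bin_estimates[mi, si]
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# model set + JSON serialization


@dataclass
class ModelSet:
    """The four estimators fitted on one shared calibration set."""

    linear: LinearModel
    polynomial: PolyModel
    knn: KNNModel
    mlgrid: MLGridModel

    def predict_all(self, mean, sd) -> dict[str, float]:
        return {
            "linear": predict_linear(self.linear, mean),
            "polynomial": predict_polynomial(self.polynomial, mean),
            "knn": predict_knn(
                self.knn, mean, sd if self.knn.distance_space == "mean_sd" else None
            ),
            "mlgrid": predict_mlgrid(self.mlgrid, mean, sd),
        }


def fit_all(
    cal: CalibrationSet,
    k: int = DEFAULT_K,
    training_fraction: float = DEFAULT_TRAINING_FRACTION,
    distance_space: str = "mean_only",
    n_bins: int = DEFAULT_N_BINS,
    bin_estimate: str = "normal_mle",
    seed: int = 0,
) -> ModelSet:
    return ModelSet(
        linear=fit_linear(cal),
        polynomial=fit_polynomial(cal),
        knn=fit_knn(cal, k=k, training_fraction=training_fraction,
                    distance_space=distance_space, seed=seed),
        mlgrid=fit_mlgrid(cal, n_bins=n_bins, bin_estimate=bin_estimate),
    )


def _nan_to_none(arr: np.ndarray) -> list:
    return [[None if math.isnan(v) else v for v in row] for row in arr.tolist()]


def _none_to_nan(rows: list) -> np.ndarray:
    return np.array([[np.nan if v is None else v for v in row] for row in rows])


def model_to_dict(model) -> dict:
    if isinstance(model, LinearModel):
        return {
            "kind": "linear",
            "intercept": model.intercept,
            "slope": model.slope,
            "r_squared": model.r_squared,
            "n": model.n,
            "slope_stderr": model.slope_stderr,
            "fitted_range": list(model.fitted_range),
        }
    if isinstance(model, PolyModel):
        return {
            "kind": "polynomial",
            "degree": model.degree,
            "coefficients": list(model.coefficients),
            "basis": model.basis,
            "scaled_coefficients": list(model.scaled_coefficients),
            "domain": list(model.domain),
            "r_squared": model.r_squared,
            "n": model.n,
            "fitted_range": list(model.fitted_range),
            "min_prediction": model.min_prediction,
            "argmin_mean": model.argmin_mean,
        }
    if isinstance(model, KNNModel):
        return {
            "kind": "knn",
            "k": model.k,
            "training_fraction": model.training_fraction,
            "distance_space": model.distance_space,
            "seed": model.seed,
            "train_means": model.train_means.tolist(),
            "train_sds": model.train_sds.tolist(),
            "train_env": model.train_env.tolist(),
            "train_point_ids": list(model.train_point_ids),
        }
    if isinstance(model, MLGridModel):
        return {
            "kind": "mlgrid",
            "n_bins": model.n_bins,
            "mean_edges": model.mean_edges.tolist(),
            "sd_edges": model.sd_edges.tolist(),
            "bin_estimates": _nan_to_none(model.bin_estimates),
            "bin_counts": model.bin_counts.tolist(),
            "bin_estimate": model.bin_estimate,
        }
    raise TypeError(f"not a model: {model!r}")


def model_from_dict(d: dict):
    kind = d.get("kind")
    if kind == "linear":
        return LinearModel(
            intercept=d["intercept"], slope=d["slope"], r_squared=d["r_squared"],
            n=d["n"], slope_stderr=d["slope_stderr"],
            fitted_range=tuple(d["fitted_range"]),
        )
    if kind == "polynomial":
        return PolyModel(
            degree=d["degree"], coefficients=tuple(d["coefficients"]),
            basis=d["basis"], scaled_coefficients=tuple(d["scaled_coefficients"]),
            domain=tuple(d["domain"]), r_squared=d["r_squared"], n=d["n"],
            fitted_range=tuple(d["fitted_range"]),
            min_prediction=d["min_prediction"], argmin_mean=d["argmin_mean"],
        )
    if kind == "knn":
        return KNNModel(
            k=d["k"], training_fraction=d["training_fraction"],
            distance_space=d["distance_space"], seed=d["seed"],
            train_means=np.array(d["train_means"], dtype=float),
            train_sds=np.array(d["train_sds"], dtype=float),
            train_env=np.array(d["train_env"], dtype=float),
            train_point_ids=tuple(d["train_point_ids"]),
        )
    if kind == "mlgrid":
        return MLGridModel(
            n_bins=d["n_bins"],
            mean_edges=np.array(d["mean_edges"], dtype=float),
            sd_edges=np.array(d["sd_edges"], dtype=float),
            bin_estimates=_none_to_nan(d["bin_estimates"]),
            bin_counts=np.array(d["bin_counts"], dtype=int),
            bin_estimate=d["bin_estimate"],
        )
    raise ValidationError(f"unknown model kind {kind!r}")


def modelset_to_dict(models: ModelSet) -> dict:
    return {
        "linear": model_to_dict(models.linear),
        "polynomial": model_to_dict(models.polynomial),
        "knn": model_to_dict(models.knn),
        "mlgrid": model_to_dict(models.mlgrid),
    }


def modelset_from_dict(d: dict) -> ModelSet:
    return ModelSet(
        linear=model_from_dict(d["linear"]),
        polynomial=model_from_dict(d["polynomial"]),
        knn=model_from_dict(d["knn"]),
        mlgrid=model_from_dict(d["mlgrid"]),
    )
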