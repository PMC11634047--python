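"""FRS-indexed fall-rate curve: smoothing, model fitting, threshold inversion.

The raw (FRS at T1, weekly fall rate over T1->T2) scatter is noisy because
most observations contain zero or one fall.  A running average over a fixed
FRS window turns it into a smooth curve; candidate regression families
(linear, quadratic, exponential) are fitted to the smoothed points and the
family with the lowest RMSE is selected.  Inverting the selected model at
"one expected fall within H weeks" yields clinically interpretable score
thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: Default smoothing window width, in FRS percentage points (2% of the
#: 0-100 scale), centred on each grid value.
DEFAULT_WINDOW = 2.0

MODEL_FAMILIES = ("linear", "quadratic", "exponential")

#: Clinically motivated projection horizons, in weeks (6 / 12 / 24 months).
DEFAULT_HORIZONS = (26, 52, 104)


class EmptyCurveError(ValueError):
    """No observations were available to smooth."""


class InsufficientDataError(ValueError):
    """Too few smoothed points to fit the requested model families."""


class ModelSelectionError(ValueError):
    """No converged candidate model to select from."""


@dataclass(frozen=True)
class SmoothedCurve:
    """Ordered (FRS, mean weekly fall rate) points from the running average."""

    frs: np.ndarray
    rate: np.ndarray
    counts: np.ndarray
    window: float

    def __post_init__(self) -> None:
        if len(self.frs) == 0:
            raise EmptyCurveError("smoothed curve has no points")
        if not np.all(np.diff(self.frs) > 0):
            raise ValueError("curve points must be strictly ordered by FRS")
        if (self.counts < 1).any():
            raise ValueError("every window must contain at least one observation")
        if (self.rate < 0).any():
            raise ValueError("fall rates cannot be negative")

    def __len__(self) -> int:
        return len(self.frs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frs": self.frs, "rate_per_week": self.rate, "n_window": self.counts}
        )


@dataclass
class FittedModel:
    """A candidate rate model fitted to the smoothed curve.

    ``coefficients`` are family-specific: ``(slope, intercept)`` for linear,
    ``(a, b, c)`` for the quadratic ``a*FRS**2 + b*FRS + c``, and ``(a, b, c)``
    for the exponential ``a*exp(b*FRS) + c``.
    """

    family: str
    coefficients: tuple[float, ...]
    rmse: float = math.nan
    converged: bool = True
    n_points: int = 0
    note: str = ""

    N_PARAMS = {"linear": 2, "quadratic": 3, "exponential": 3}

    def predict(self, frs) -> np.ndarray:
        x = np.asarray(frs, dtype=float)
        c = self.coefficients
        if self.family == "linear":
            return c[0] * x + c[1]
        if self.family == "quadratic":
            return c[0] * x**2 + c[1] * x + c[2]
        if self.family == "exponential":
            return c[0] * np.exp(c[1] * x) + c[2]
        raise ValueError(f"unknown model family {self.family!r}")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "coefficients": list(self.coefficients),
            "rmse": self.rmse,
            "converged": self.converged,
            "n_points": self.n_points,
            "note": self.note,
        }


@dataclass(frozen=True)
class CurveAssociation:
    """Spearman rank correlation of the smoothed (FRS, rate) points."""

    rho: float | None
    p_value: float | None
    n_points: int
    degenerate: bool = False


def running_average(
    frs_t1,
    rate_per_week,
    window: float = DEFAULT_WINDOW,
    adaptive: bool = False,
) -> SmoothedCurve:
    """Smooth observations into a mean fall rate per integer FRS value.

    For each distinct integer FRS value present in the data, the smoothed
    rate is the mean weekly fall rate over all observations whose T1 FRS lies
    within ``window / 2`` points of that value (closed interval).  With
    ``adaptive=True`` the half-width instead scales with the local score,
    ``(window / 100) * value / 2``, i.e. "window % of the FRS value"; the
    fixed reading is the default because a proportional window degenerates to
    zero width near FRS 0.

    Accepts either two array-likes or a pairs frame via
    ``running_average(pairs["frs_t1"], pairs["rate_per_week"])``.
    """
    x = np.asarray(frs_t1, dtype=float)
    y = np.asarray(rate_per_week, dtype=float)
    if x.size == 0:
        raise EmptyCurveError("no observations to smooth")
    if window <= 0:
        raise ValueError("window must be positive")

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    csum = np.concatenate([[0.0], np.cumsum(ys)])

    grid = np.unique(np.rint(xs))
    half = np.where(
        adaptive, (window / 100.0) * grid / 2.0, np.full_like(grid, window / 2.0)
    ).astype(float)
    lo = np.searchsorted(xs, grid - half, side="left")
    hi = np.searchsorted(xs, grid + half, side="right")
    counts = hi - lo
    nonempty = counts > 0
    means = np.full(grid.shape, np.nan)
    means[nonempty] = (csum[hi] - csum[lo])[nonempty] / counts[nonempty]
    return SmoothedCurve(
        frs=grid[nonempty],
        rate=means[nonempty],
        counts=counts[nonempty],
        window=window,
    )


def _fit_polynomial(curve: SmoothedCurve, degree: int) -> tuple[tuple[float, ...], float]:
    coef = np.polyfit(curve.frs, curve.rate, degree)
    resid = np.polyval(coef, curve.frs) - curve.rate
    return tuple(float(c) for c in coef), float(np.sqrt(np.mean(resid**2)))


def _fit_exponential(curve: SmoothedCurve) -> FittedModel:
    # a*exp(b*x)+c; init: amplitude = rate range, gentle growth, offset = min.
    y = curve.rate
    p0 = (max(float(y.max() - y.min()), 1e-6), 0.01, float(y.min()))
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, b, c: a * np.exp(b * x) + c,
            curve.frs,
            y,
            p0=p0,
            maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        logger.warning("exponential fit did not converge: %s", exc)
        return FittedModel(
            family="exponential",
            coefficients=p0,
            rmse=math.inf,
            converged=False,
            n_points=len(curve),
            note=f"non-converged: {exc}",
        )
    model = FittedModel("exponential", tuple(float(v) for v in popt), n_points=len(curve))
    resid = model.predict(curve.frs) - y
    model.rmse = float(np.sqrt(np.mean(resid**2)))
    if not np.isfinite(model.rmse):
        model.converged = False
        model.rmse = math.inf
        model.note = "non-finite residuals"
    return model


def fit_models(
    curve: SmoothedCurve,
    families: tuple[str, ...] = MODEL_FAMILIES,
) -> list[FittedModel]:
    """Fit each candidate family to the smoothed points and attach its RMSE.

    Linear and quadratic use ordinary least squares; the exponential
    ``a*exp(b*FRS) + c`` uses Levenberg-Marquardt nonlinear least squares.
    A nonlinear fit that fails to converge is returned flagged
    (``converged=False``, infinite RMSE) rather than silently dropped.
    """
    unknown = set(families) - set(MODEL_FAMILIES)
    if unknown:
        raise ValueError(f"unknown model families: {sorted(unknown)}")
    min_points = max(FittedModel.N_PARAMS[f] for f in families) + 1
    if len(curve) < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} smoothed points for {families}, got {len(curve)}"
        )
    models: list[FittedModel] = []
    for family in families:
        if family == "linear":
            coef, rmse = _fit_polynomial(curve, 1)
            models.append(FittedModel("linear", coef, rmse, n_points=len(curve)))
        elif family == "quadratic":
            coef, rmse = _fit_polynomial(curve, 2)
            models.append(FittedModel("quadratic", coef, rmse, n_points=len(curve)))
        else:
            models.append(_fit_exponential(curve))
    return models


def select_model(models: list[FittedModel]) -> FittedModel:
    """Select the converged model with the lowest RMSE.

    Exact RMSE ties are broken toward the family with fewer parameters, then
    by the declared order linear < quadratic < exponential; a tie-break is
    logged so the selection is auditable.
    """
    converged = [m for m in models if m.converged]
    if not converged:
        raise ModelSelectionError("no converged model to select from")
    order = {f: i for i, f in enumerate(MODEL_FAMILIES)}
    best = min(
        converged,
        key=lambda m: (m.rmse, m.N_PARAMS[m.family], order[m.family]),
    )
    ties = [m for m in converged if m.rmse == best.rmse and m is not best]
    if ties:
        logger.info(
            "RMSE tie between %s; selected %s (fewer parameters / declared order)",
            [m.family for m in ties + [best]],
            best.family,
        )
    return best


def spearman_on_curve(curve: SmoothedCurve) -> CurveAssociation:
    """Spearman rank correlation (average-rank ties, two-sided p) of the
    smoothed points.

    A constant rate vector has no defined rank correlation; it is returned as
    an explicitly flagged degenerate result instead of propagating NaN.
    """
    if len(curve) < 3:
        raise InsufficientDataError("need >= 3 smoothed points for a correlation")
    if np.all(curve.rate == curve.rate[0]):
        return CurveAssociation(None, None, len(curve), degenerate=True)
    res = stats.spearmanr(curve.frs, curve.rate)
    return CurveAssociation(float(res.statistic), float(res.pvalue), len(curve))


def threshold_frs(model: FittedModel, horizon_weeks: int) -> int | None:
    """Smallest integer FRS at which the model expects >= 1 fall in a horizon.

    Solves ``rate(FRS) * horizon_weeks = 1`` and rounds the positive root up
    to the next integer percent ("risk starting at ...").  Returns ``None``
    when the expected fall count never reaches 1 anywhere on the 0-100 scale.
    """
    if horizon_weeks <= 0:
        raise ValueError("horizon must be a positive number of weeks")
    target = 1.0 / horizon_weeks
    if model.family == "quadratic":
        a, b, c = model.coefficients
        if a <= 0:
            raise ValueError("threshold inversion requires a positive leading coefficient")
        disc = b * b - 4.0 * a * (c - target)
        if disc < 0:
            return None
        root = (-b + math.sqrt(disc)) / (2.0 * a)
    else:
        # Monotone families: scan the integer scale for the first crossing.
        grid = np.arange(0, 101)
        hits = np.nonzero(model.predict(grid) >= target)[0]
        root = float(grid[hits[0]]) if hits.size else math.inf
    if root > 100:
        return None
    return max(0, math.ceil(root))
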