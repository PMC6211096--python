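"""Logistic calibration of defoliation fraction against index change.

Model
-----
The observed defoliated fraction Y of a cell (bounded in [0, 1]) is related
to the index-change predictor X by a two-parameter logistic curve

    Y = 1 / (1 + exp(-(a + b X)))

with intercept ``a`` and slope ``b``.  Because Y is a fraction rather than a
0/1 outcome, the fit maximizes the fractional-response Bernoulli
quasi-log-likelihood

    l(a, b) = sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ],

which is well defined at y in {0, 1} and concave in (a, b), so a damped
Newton iteration from a fixed start converges deterministically.  Goodness of
fit is McFadden's pseudo R^2 on the deviance scale,

    R^2 = 1 - (l_sat - l_full) / (l_sat - l_null),

where the null model is the intercept-only logistic (constant p = mean y)
and l_sat is the saturated quasi-likelihood (p_i = y_i).  For 0/1 outcomes
l_sat = 0 and this reduces to the classical 1 - l_full / l_null; for
fractional responses the saturated term removes the irreducible entropy of
the interpreted fractions, which a perfect fit cannot explain.

Inverting the fitted curve at defoliation fractions Y in {0.10, 0.35, 0.70}
via  X = (ln(Y / (1 - Y)) - a) / b  yields the X threshold limits that
separate the nil/low/medium/high severity classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logit, xlogy

from .errors import ConfigurationError, ConvergenceError, DataError
from .util import round_half_away

DEFAULT_BOUNDARIES_Y = (0.10, 0.35, 0.70)

#: slope sign each index is physically expected to carry in a pre-minus-post
#: change raster: moisture-stress style indices (MID, MSI) rise with canopy
#: loss, so their change is negative under defoliation; greenness/moisture
#: normalized differences fall, so their change is positive.
EXPECTED_SLOPE_SIGN = {"MID": -1, "MSI": -1, "NDMI": +1, "NDVI": +1, "NBR": +1}


def logistic_forward(a: float, b: float, x) -> float | np.ndarray:
    """Evaluate Y = 1/(1 + e^-(a + bX)) overflow-safely."""
    out = expit(a + b * np.asarray(x, dtype=float))
    if out.ndim == 0:
        return float(out)
    return out


def _quasi_loglik(y, p) -> float:
    return float(np.sum(xlogy(y, p) + xlogy(1.0 - y, 1.0 - p)))


@dataclass
class LogisticFit:
    """Fitted logistic calibration for one index-change predictor."""

    index_name: str
    a: float
    b: float
    r2_mcfadden: float
    n: int
    loglik_full: float
    loglik_null: float
    loglik_sat: float = 0.0
    n_iter: int = 0

    def predict(self, x):
        return logistic_forward(self.a, self.b, x)


@dataclass
class ThresholdSet:
    """X threshold limits at the severity boundaries of one fitted model.

    ``limits_x`` holds the unrounded inversions (used for classification);
    ``limits_x_rounded`` is the display form, rounded ties-away-from-zero.
    Orientation follows the slope sign: a negative slope means larger
    defoliation maps to smaller X (decreasing).
    """

    index_name: str
    boundaries_y: tuple = DEFAULT_BOUNDARIES_Y
    limits_x: tuple = ()
    orientation: str = "decreasing"

    def __post_init__(self):
        if self.orientation not in ("decreasing", "increasing"):
            raise ConfigurationError(f"bad orientation {self.orientation!r}")
        if len(self.limits_x) != len(self.boundaries_y):
            raise ConfigurationError("limits_x and boundaries_y lengths differ")
        diffs = np.diff(self.limits_x)
        if self.orientation == "decreasing" and not np.all(diffs < 0):
            raise DataError(f"limits {self.limits_x} not strictly decreasing")
        if self.orientation == "increasing" and not np.all(diffs > 0):
            raise DataError(f"limits {self.limits_x} not strictly increasing")

    @property
    def limits_x_rounded(self) -> tuple[int, ...]:
        return tuple(int(round_half_away(v)) for v in self.limits_x)


def _as_xy(samples):
    """Accept a list of CalibrationSample or an (x, y) pair of arrays."""
    if isinstance(samples, tuple) and len(samples) == 2:
        x, y = samples
    else:
        x = [s.x for s in samples]
        y = [s.y for s in samples]
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def fit_logistic(
    samples,
    index_name: str = "",
    gtol: float = 1e-8,
    max_iter: int = 200,
) -> LogisticFit:
    """Maximum-quasi-likelihood logistic fit of fraction y on predictor x.

    Deterministic: the predictor is standardized internally, the iteration
    starts at (logit(mean y), 0) and runs damped Newton steps until the
    gradient (on the standardized scale) drops below ``gtol``.

    Raises :class:`DataError` on degenerate inputs (fewer than 4 samples,
    constant x, constant y) and :class:`ConvergenceError`, with the
    iteration trace attached, if the gradient tolerance is not reached.
    """
    x, y = _as_xy(samples)
    n = x.size
    if n < 4:
        raise DataError(f"need at least 4 samples, got {n}")
    if y.size != n:
        raise DataError("x and y lengths differ")
    if np.any((y < 0) | (y > 1)):
        raise DataError("y values outside [0, 1]")
    if np.ptp(x) == 0:
        raise DataError("all x values equal; slope unidentifiable")
    if np.ptp(y) == 0:
        raise DataError("all y values equal; degenerate likelihood")

    ybar = float(y.mean())
    xbar, xsd = float(x.mean()), float(x.std())
    z = (x - xbar) / xsd

    alpha = float(logit(np.clip(ybar, 1e-12, 1 - 1e-12)))
    beta = 0.0
    ll = _quasi_loglik(y, expit(alpha + beta * z))
    trace = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = expit(alpha + beta * z)
        resid = y - p
        g = np.array([resid.sum(), (resid * z).sum()])
        trace.append({"iter": n_iter, "grad_max": float(np.abs(g).max()), "loglik": ll})
        if np.abs(g).max() < gtol:
            break
        w = p * (1.0 - p) + 1e-12
        H = np.array([[w.sum(), (w * z).sum()], [(w * z).sum(), (w * z * z).sum()]])
        step = np.linalg.solve(H, g)
        t = 1.0
        while t > 1e-10:
            cand = expit((alpha + t * step[0]) + (beta + t * step[1]) * z)
            ll_new = _quasi_loglik(y, cand)
            if ll_new >= ll - 1e-13:
                break
            t /= 2.0
        alpha += t * step[0]
        beta += t * step[1]
        ll = _quasi_loglik(y, expit(alpha + beta * z))
    else:
        raise ConvergenceError(
            f"logistic fit did not reach gtol={gtol} in {max_iter} iterations", trace
        )

    b = beta / xsd
    a = alpha - beta * xbar / xsd
    loglik_full = _quasi_loglik(y, expit(a + b * x))
    loglik_null = _quasi_loglik(y, np.full_like(y, ybar))
    loglik_sat = _quasi_loglik(y, y)
    fit = LogisticFit(
        index_name=index_name,
        a=float(a),
        b=float(b),
        r2_mcfadden=0.0,
        n=int(n),
        loglik_full=loglik_full,
        loglik_null=loglik_null,
        loglik_sat=loglik_sat,
        n_iter=n_iter,
    )
    fit.r2_mcfadden = mcfadden_r2(fit)
    return fit


def mcfadden_r2(fit: LogisticFit) -> float:
    """McFadden pseudo R^2 = 1 - (l_sat - l_full) / (l_sat - l_null), clipped to [0, 1].

    ``l_sat`` is 0 for 0/1 outcomes, recovering the classical 1 - l_full/l_null.
    """
    if fit.loglik_null == 0.0:
        raise DataError("null log-likelihood is zero")
    if fit.loglik_null > 0.0:
        raise DataError("null log-likelihood must be negative")
    denom = fit.loglik_sat - fit.loglik_null
    if denom == 0.0:
        raise DataError("null deviance is zero; McFadden R^2 undefined")
    return float(np.clip(1.0 - (fit.loglik_sat - fit.loglik_full) / denom, 0.0, 1.0))


def invert_threshold(fit: LogisticFit, y: float) -> float:
    """Solve the fitted curve for X at fraction y: X = (logit(y) - a) / b."""
    if not 0.0 < y < 1.0:
        raise ConfigurationError(f"boundary fraction {y} must lie strictly in (0, 1)")
    if fit.b == 0.0:
        raise ConfigurationError("slope b is zero; curve cannot be inverted")
    return (float(np.log(y / (1.0 - y))) - fit.a) / fit.b


def derive_threshold_set(fit: LogisticFit, boundaries_y=DEFAULT_BOUNDARIES_Y) -> ThresholdSet:
    """Invert a fit at each class-boundary fraction (default 0.10/0.35/0.70)."""
    limits = tuple(invert_threshold(fit, y) for y in boundaries_y)
    return ThresholdSet(
        index_name=fit.index_name,
        boundaries_y=tuple(boundaries_y),
        limits_x=limits,
        orientation="decreasing" if fit.b < 0 else "increasing",
    )


@dataclass
class ModelRanking:
    """Fits ordered by McFadden R^2 (descending), ties broken by index name."""

    fits: list
    ties: list = field(default_factory=list)  # index-name pairs with equal R^2

    @property
    def best(self) -> LogisticFit:
        return self.fits[0]


def compare_models(fits: list[LogisticFit]) -> ModelRanking:
    """Rank candidate index models by goodness of fit."""
    if not fits:
        raise ConfigurationError("no fits to compare")
    ordered = sorted(fits, key=lambda f: (-f.r2_mcfadden, f.index_name))
    ties = [
        (ordered[i].index_name, ordered[i + 1].index_name)
        for i in range(len(ordered) - 1)
        if ordered[i].r2_mcfadden == ordered[i + 1].r2_mcfadden
    ]
    return ModelRanking(fits=ordered, ties=ties)


# ---------------------------------------------------------------------------
# JSON interchange


def fit_to_dict(fit: LogisticFit) -> dict:
    return {
        "index_name": fit.index_name,
        "a": fit.a,
        "b": fit.b,
        "r2_mcfadden": fit.r2_mcfadden,
        "n": fit.n,
        "loglik_full": fit.loglik_full,
        "loglik_null": fit.loglik_null,
        "loglik_sat": fit.loglik_sat,
        "n_iter": fit.n_iter,
    }


def fit_from_dict(d: dict) -> LogisticFit:
    return LogisticFit(
        index_name=d.get("index_name", ""),
        a=float(d["a"]),
        b=float(d["b"]),
        r2_mcfadden=float(d.get("r2_mcfadden", 0.0)),
        n=int(d.get("n", 0)),
        loglik_full=float(d.get("loglik_full", 0.0)),
        loglik_null=float(d.get("loglik_null", -1.0)),
        loglik_sat=float(d.get("loglik_sat", 0.0)),
        n_iter=int(d.get("n_iter", 0)),
    )


def write_fit_json(path, fit: LogisticFit) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=1, sort_keys=True) + "\n")


def read_fit_json(path) -> LogisticFit:
    return fit_from_dict(json.loads(Path(path).read_text()))


def thresholds_to_dict(ts: ThresholdSet) -> dict:
    return {
        "index_name": ts.index_name,
        "boundaries_y": list(ts.boundaries_y),
        "limits_x_raw": list(ts.limits_x),
        "limits_x_rounded": list(ts.limits_x_rounded),
        "orientation": ts.orientation,
    }


def write_thresholds_json(path, ts: ThresholdSet) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(thresholds_to_dict(ts), indent=1, sort_keys=True) + "\n")


def read_thresholds_json(path) -> ThresholdSet:
    d = json.loads(Path(path).read_text())
    return ThresholdSet(
        index_name=d.get("index_name", ""),
        boundaries_y=tuple(d["boundaries_y"]),
        limits_x=tuple(d["limits_x_raw"]),
        orientation=d["orientation"],
    )


def slope_sign_warning(fit: LogisticFit) -> str | None:
    """Warn when a fitted slope sign conflicts with the index's physical expectation.

    A conflicting sign flips the threshold orientation, so downstream maps
    classify in the opposite direction; the magnitudes of the inverted
    thresholds are unaffected.
    """
    base = fit.index_name[1:] if fit.index_name.startswith("d") else fit.index_name
    expected = EXPECTED_SLOPE_SIGN.get(base.upper())
    if expected is None or fit.b == 0:
        return None
    if np.sign(fit.b) != expected:
        return (
            f"{fit.index_name}: slope {fit.b:+.7g} has the opposite sign of the "
            f"expected {'negative' if expected < 0 else 'positive'} response; "
            "threshold limits are reported signed, compare magnitudes with care"
        )
    return None
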