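"""BMI-category trend fitting, projection and individual assignment.

Sparse cross-sectional surveys give the share of each WHO BMI class
(healthy / pre-obese / obese) per (sex, five-year age band) at a handful of
years. We fit, separately per stratum, a multinomial (softmax) model of the
category probabilities against calendar time, weighted by survey sample
size, and project it over the simulation horizon.

Two functional forms are supported for the non-reference log-odds
``eta_c(t)`` (healthy is the reference, ``eta_healthy = 0``):

``linear``
    ``eta_c(t) = a_c + b_c * (t - 2010)`` — log-odds linear in time;
    identifiable from two distinct survey years.
``saturating``
    ``eta_c(t) = a_c + b_c * (1 - exp(-k (t - 2010))) / k`` with a shared
    rate ``k > 0`` — reduces to the linear form as ``k -> 0`` and levels
    off at ``a_c + b_c / k`` for large ``t``, so long-horizon projections
    are bounded; needs three distinct survey years.

Individuals carry a fixed BMI percentile rank in (0,1); category assignment
is by rank quantile against the projected probabilities, so an individual's
category evolves smoothly (and monotonically in rank) as the marginal
distribution shifts. The zero-obesity counterfactual maps every probability
vector to (1, 0, 0).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import CoverageError, UnderDeterminedError
from .strata import CATEGORIES, HEALTHY

#: time origin for the trend covariate (keeps coefficients well-scaled)
TIME_ORIGIN = 2010.0

#: default log-odds floor for categories observed identically at zero
DEFAULT_LOGODDS_FLOOR = -20.0

_NONREF = (1, 2)  # pre_obese, obese


@dataclass(frozen=True)
class SurveyPoint:
    """One cross-sectional survey estimate for one (sex, age band) stratum."""

    year: int
    sex: str
    age_group: str
    proportions: tuple[float, float, float]  # healthy, pre_obese, obese
    n_sample: int

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (3,):
            raise ValueError("proportions must be a 3-vector")
        if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"proportions must lie in [0,1] and sum to 1, got {tuple(p)}"
            )
        if self.n_sample < 1:
            raise ValueError("n_sample must be >= 1")


@dataclass
class StratumFit:
    """Fitted trend for one (sex, age band) stratum."""

    form: str
    params: np.ndarray  # linear: (a_pre, b_pre, a_ob, b_ob); saturating: + log k
    cov: np.ndarray | None  # covariance of params (linear form only)
    deviance: float
    residuals: np.ndarray  # (n_points, 3) observed minus fitted proportions
    years: np.ndarray
    fixed_floor: tuple[bool, bool]  # per non-reference category

    def log_odds(self, year: float | np.ndarray, floor: float) -> np.ndarray:
        """Non-reference log-odds (eta_pre, eta_obese) at ``year``."""
        tau = np.asarray(year, dtype=float) - TIME_ORIGIN
        if self.form == "linear":
            a = self.params[0::2][:2]
            b = self.params[1::2][:2]
            g = tau
        else:
            a = self.params[0:4:2]
            b = self.params[1:4:2]
            k = np.exp(self.params[4])
            g = -np.expm1(-k * tau) / k
        eta = a[..., :] + np.multiply.outer(g, b) if np.ndim(tau) else a + b * g
        for ci, fixed in enumerate(self.fixed_floor):
            if fixed:
                eta[..., ci] = floor if np.ndim(tau) == 0 else floor
        return np.clip(eta, floor, -floor)


class CategoryTrendModel:
    """Collection of per-stratum fitted BMI-category trends."""

    def __init__(self, fits: dict[tuple[str, str], StratumFit], form: str, floor: float):
        self.fits = fits
        self.form = form
        self.floor = floor

    def strata(self) -> list[tuple[str, str]]:
        return sorted(self.fits)

    def predict(self, sex: str, age_group: str, year: float) -> np.ndarray:
        """Simplex 3-vector of category probabilities at ``year``."""
        try:
            fit = self.fits[(sex, age_group)]
        except KeyError:
            raise CoverageError(
                f"no fitted BMI trend for stratum ({sex}, {age_group})"
            ) from None
        eta = fit.log_odds(year, self.floor)
        return _softmax3(eta[0], eta[1])

    def slope(self, sex: str, age_group: str, category: str) -> float:
        """Fitted per-year time slope on the log-odds scale."""
        fit = self.fits[(sex, age_group)]
        ci = CATEGORIES.index(category) - 1
        if ci < 0:
            raise ValueError("healthy is the reference category; it has no slope")
        return float(fit.params[2 * ci + 1])

    def slope_interval(
        self, sex: str, age_group: str, category: str, level: float = 0.95
    ) -> tuple[float, float]:
        """Wald confidence interval for a time slope (linear form only)."""
        fit = self.fits[(sex, age_group)]
        if fit.cov is None:
            raise ValueError("slope intervals are available for the linear form only")
        ci = CATEGORIES.index(category) - 1
        if ci < 0:
            raise ValueError("healthy is the reference category; it has no slope")
        b = fit.params[2 * ci + 1]
        se = float(np.sqrt(max(fit.cov[2 * ci + 1, 2 * ci + 1], 0.0)))
        z = stats.norm.ppf(0.5 + level / 2)
        return (b - z * se, b + z * se)


def _softmax3(eta_pre: float | np.ndarray, eta_ob: float | np.ndarray) -> np.ndarray:
    """Probabilities (healthy, pre_obese, obese) from non-reference log-odds."""
    eta = np.stack(
        [np.zeros_like(np.asarray(eta_pre, dtype=float)), np.asarray(eta_pre, float), np.asarray(eta_ob, float)],
        axis=-1,
    )
    eta -= eta.max(axis=-1, keepdims=True)
    ex = np.exp(eta)
    return ex / ex.sum(axis=-1, keepdims=True)


def _design(tau: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(tau), tau])


def _nll_linear(theta: np.ndarray, X: np.ndarray, phat: np.ndarray, w: np.ndarray,
                free: np.ndarray, floor: float) -> tuple[float, np.ndarray]:
    """Weighted multinomial negative log-likelihood and gradient, linear form.

    ``theta`` holds (a_pre, b_pre, a_ob, b_ob); entries where ``free`` is
    False are held at (floor, 0).
    """
    a = np.where(free[[0, 2]], theta[[0, 2]], floor)
    b = np.where(free[[1, 3]], theta[[1, 3]], 0.0)
    eta = X @ np.column_stack([a, b]).T  # (J, 2)
    p = _softmax3(eta[:, 0], eta[:, 1])  # (J, 3)
    logp = np.log(np.clip(p, 1e-300, 1.0))
    nll = -float(np.sum(w[:, None] * phat * logp))
    # gradient wrt (a_c, b_c): sum_j w_j (p_jc - phat_jc) x_j
    resid = w[:, None] * (p[:, 1:] - phat[:, 1:])  # (J, 2)
    grad = np.empty(4)
    grad[0::2] = resid.T @ X[:, 0]
    grad[1::2] = resid.T @ X[:, 1]
    grad[~free] = 0.0
    return nll, grad


def _hessian_linear(theta: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Analytic observed information for the linear multinomial model."""
    a = theta[[0, 2]]
    b = theta[[1, 3]]
    eta = X @ np.column_stack([a, b]).T
    p = _softmax3(eta[:, 0], eta[:, 1])
    H = np.zeros((4, 4))
    for j in range(len(w)):
        pj = p[j, 1:]
        W = np.diag(pj) - np.outer(pj, pj)  # 2x2 multinomial covariance block
        xx = np.outer(X[j], X[j])  # 2x2 in (1, tau)
        # parameter order (a_pre, b_pre, a_ob, b_ob) = kron(category, design)
        H += w[j] * np.kron(W, xx)
    return H


def _nll_saturating(theta: np.ndarray, tau: np.ndarray, phat: np.ndarray,
                    w: np.ndarray, free: np.ndarray, floor: float) -> float:
    a = np.where(free[[0, 2]], theta[[0, 2]], floor)
    b = np.where(free[[1, 3]], theta[[1, 3]], 0.0)
    k = np.exp(theta[4])
    g = -np.expm1(-k * tau) / k
    eta = np.column_stack([a[0] + b[0] * g, a[1] + b[1] * g])
    p = _softmax3(eta[:, 0], eta[:, 1])
    logp = np.log(np.clip(p, 1e-300, 1.0))
    return -float(np.sum(w[:, None] * phat * logp))


def _init_logodds(tau: np.ndarray, phat: np.ndarray, w: np.ndarray, floor: float) -> np.ndarray:
    """Weighted least squares on observed log-odds as a starting point."""
    ph = np.clip(phat, 1e-12, 1.0)
    y = np.log(ph[:, 1:] / ph[:, [0]])
    y = np.clip(y, floor, -floor)
    X = _design(tau)
    W = np.diag(w)
    beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(W) @ y, rcond=None)
    return np.array([beta[0, 0], beta[1, 0], beta[0, 1], beta[1, 1]])


def fit_category_trend(
    points: list[SurveyPoint],
    form: str = "saturating",
    floor: float = DEFAULT_LOGODDS_FLOOR,
) -> CategoryTrendModel:
    """Fit per-stratum multinomial time trends to survey points.

    Points are grouped by (sex, age band); each stratum is fitted by maximum
    likelihood with points weighted by their survey sample size. A category
    observed identically at zero across a stratum's points is pinned at the
    log-odds floor (slope zero) with a warning.
    """
    if form not in ("linear", "saturating"):
        raise ValueError(f"unknown functional form {form!r}")
    if not points:
        raise ValueError("no survey points supplied")
    min_years = 2 if form == "linear" else 3

    grouped: dict[tuple[str, str], list[SurveyPoint]] = {}
    for pt in points:
        grouped.setdefault((pt.sex, pt.age_group), []).append(pt)

    fits: dict[tuple[str, str], StratumFit] = {}
    for key, pts in grouped.items():
        years = np.array([p.year for p in pts], dtype=float)
        if len(np.unique(years)) < min_years:
            raise UnderDeterminedError(
                f"stratum {key} has {len(np.unique(years))} distinct survey years; "
                f"the {form} form needs at least {min_years}"
            )
        tau = years - TIME_ORIGIN
        phat = np.array([p.proportions for p in pts], dtype=float)
        w = np.array([p.n_sample for p in pts], dtype=float)

        fixed = tuple(bool(np.all(phat[:, c] == 0.0)) for c in _NONREF)
        if any(fixed):
            dead = [CATEGORIES[c] for c, fx in zip(_NONREF, fixed) if fx]
            warnings.warn(
                f"stratum {key}: categories {dead} observed at zero in every survey; "
                f"pinned at log-odds floor {floor}",
                stacklevel=2,
            )
        free4 = np.array(
            [not fixed[0], not fixed[0], not fixed[1], not fixed[1]], dtype=bool
        )

        theta0 = _init_logodds(tau, phat, w, floor)
        if form == "linear":
            X = _design(tau)
            res = optimize.minimize(
                _nll_linear, theta0, args=(X, phat, w, free4, floor),
                jac=True, method="BFGS",
                options={"gtol": 1e-10, "maxiter": 500},
            )
            params = np.where(free4, res.x, np.where([0, 1, 0, 1], 0.0, floor))
            cov = None
            if free4.all():
                H = _hessian_linear(params, X, w)
                try:
                    cov = np.linalg.inv(H)
                except np.linalg.LinAlgError:
                    cov = np.linalg.pinv(H)
            nll = res.fun
        else:
            theta0 = np.append(theta0, np.log(0.05))  # near-linear start
            res = optimize.minimize(
                _nll_saturating, theta0, args=(tau, phat, w, free4, floor),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            params = res.x.copy()
            params[:4] = np.where(free4, params[:4], np.where([0, 1, 0, 1], 0.0, floor))
            cov = None
            nll = res.fun

        fit = StratumFit(
            form=form, params=params, cov=cov, deviance=0.0,
            residuals=np.zeros_like(phat), years=years, fixed_floor=fixed,
        )
        eta = fit.log_odds(years, floor)
        fitted = _softmax3(eta[:, 0], eta[:, 1])
        fit.residuals = phat - fitted
        with np.errstate(divide="ignore", invalid="ignore"):
            sat = np.where(phat > 0, phat * np.log(phat / np.clip(fitted, 1e-300, 1)), 0.0)
        fit.deviance = float(2.0 * np.sum(w[:, None] * sat))
        fits[key] = fit

    return CategoryTrendModel(fits, form=form, floor=floor)


def project_category_probabilities(
    model: CategoryTrendModel, sex: str, age_group: str, year: float
) -> np.ndarray:
    """Deterministic simplex 3-vector of category probabilities at ``year``."""
    return model.predict(sex, age_group, year)


def apply_counterfactual(probabilities: np.ndarray) -> np.ndarray:
    """Zero-obesity counterfactual: all mass on the healthy category."""
    p = np.asarray(probabilities, dtype=float)
    if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("input must be a probability 3-vector summing to 1")
    return np.array([1.0, 0.0, 0.0])


def assign_category(bmi_rank: float, probabilities: np.ndarray) -> int:
    """Rank-preserving quantile assignment of one individual.

    healthy if ``rank < p_healthy``; pre-obese if ``rank < p_healthy + p_pre``;
    obese otherwise. Monotone in rank, so the population's category shares
    match the marginal probabilities in expectation and individuals drift
    between categories only as the marginals shift.
    """
    if not (0.0 < bmi_rank < 1.0):
        raise ValueError(f"BMI percentile rank must lie in (0, 1), got {bmi_rank}")
    p = np.asarray(probabilities, dtype=float)
    if bmi_rank < p[HEALTHY]:
        return 0
    if bmi_rank < p[HEALTHY] + p[1]:
        return 1
    return 2


def assign_categories(ranks: np.ndarray, probabilities: np.ndarray) -> np.ndarray:
    """Vectorised :func:`assign_category` for one shared probability vector."""
    ranks = np.asarray(ranks, dtype=float)
    if ((ranks <= 0.0) | (ranks >= 1.0)).any():
        raise ValueError("all BMI percentile ranks must lie in (0, 1)")
    p = np.asarray(probabilities, dtype=float)
    t1 = p[0]
    t2 = p[0] + p[1]
    return ((ranks >= t1).astype(np.int8) + (ranks >= t2).astype(np.int8))
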