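"""Smooth age-dependent distribution models (step 4 of the pipeline).

Each distribution parameter of a Box-Cox family (mu, sigma, lam and, for
BCPE/BCT, tau) is a smooth curve over transformed age ``u = log(age + 1)``,
represented by a cubic B-spline with equally spaced interior knots and a
second-order difference penalty (a P-spline).  Location-type positivity is
enforced through log links for mu, sigma and tau; lam uses the identity
link.  The fit maximizes the weighted penalized log-likelihood

    sum_i w_i * log f(y_i | theta(u_i))  -  1/2 sum_k pen_k ||D c_k||^2

over all coefficient blocks jointly (quasi-Newton), where the weights are
the probability-of-being-non-pathological weights of step 3.  Smoothing
strengths are selected per curve by the same BIC used for family selection:

    BIC = -2 * (weighted log-lik) + (total effective df) * log(sum_i w_i)

Percentiles, z-scores and serialization round out the module; the family
primitives live in :mod:`refcurve.families` and are re-exported here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy.interpolate import BSpline
from scipy.special import ndtri

from . import families
from .families import FAMILY_PARAMS, FamilyParams  # noqa: F401  (module surface)
from .core_io import (
    ExtrapolationError,
    FittingError,
    PercentileTable,
    PipelineConfig,
    PipelineError,
    ValidationError,
)

logger = logging.getLogger(__name__)

family_log_density = families.log_density
family_cdf = families.cdf
family_quantile = families.quantile

LINKS = {"mu": "log", "sigma": "log", "lam": "identity", "tau": "log"}
FAMILY_ORDER = ("BCCG", "BCPE", "BCT")

N_INTERIOR_KNOTS = 20
SPLINE_DEGREE = 3
PENALTY_GRID = tuple(np.logspace(-2.0, 4.0, 7))
DEFAULT_PENALTY = 10.0
MIN_WEIGHTED_POINTS = 500
_ETA_CLIP = 35.0
_TAU_ETA_CLIP = 8.0  # tau in [e^-8, e^8]; beyond ~3000 the normal limit holds


def age_transform(age_days) -> np.ndarray:
    """u = log(age_days + 1): compresses the neonatal range where dynamics
    are most pronounced."""
    return np.log(np.asarray(age_days, dtype=float) + 1.0)


def make_knots(u_min: float, u_max: float, n_interior: int = N_INTERIOR_KNOTS) -> np.ndarray:
    """Clamped cubic knot vector with equally spaced interior knots.

    Degenerate (zero-width) u-ranges collapse to a single constant basis
    function, handled by :func:`design_matrix`.
    """
    if u_max - u_min < 1e-9:
        return np.array([u_min])  # sentinel: constant basis
    interior = np.linspace(u_min, u_max, n_interior + 2)[1:-1]
    k = SPLINE_DEGREE
    return np.concatenate([[u_min] * (k + 1), interior, [u_max] * (k + 1)])


def design_matrix(u: np.ndarray, knots: np.ndarray) -> np.ndarray:
    if len(knots) == 1:  # constant basis for degenerate age range
        return np.ones((len(u), 1))
    k = SPLINE_DEGREE
    lo, hi = knots[k], knots[-k - 1]
    uc = np.clip(u, lo, hi)
    return BSpline.design_matrix(uc, knots, k).toarray()


def _difference_penalty(n_basis: int) -> np.ndarray:
    if n_basis < 3:
        return np.zeros((n_basis, n_basis))
    D = np.diff(np.eye(n_basis), n=2, axis=0)
    return D.T @ D


def _apply_link(eta: np.ndarray, link: str) -> np.ndarray:
    if link == "log":
        return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    return eta


@dataclass
class ParamCurve:
    """One distribution parameter as a penalized spline over u."""

    name: str
    link: str
    knots: np.ndarray
    coef: np.ndarray
    penalty: float
    edf: float = float("nan")

    def eta(self, u: np.ndarray) -> np.ndarray:
        return design_matrix(np.asarray(u, dtype=float), self.knots) @ self.coef

    def value(self, u: np.ndarray) -> np.ndarray:
        return _apply_link(self.eta(u), self.link)


@dataclass
class ContinuousModel:
    """A fitted family with smooth parameter curves over age."""

    family: str
    curves: dict
    age_min: int
    age_max: int
    loglik: float
    bic: float
    n_eff: float
    analyte_label: str = "analyte"
    unit_label: str = "a.u."

    @property
    def total_edf(self) -> float:
        return float(sum(c.edf for c in self.curves.values()))

    def _check_ages(self, ages) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages))
        if np.any(ages < self.age_min) or np.any(ages > self.age_max):
            raise ExtrapolationError(
                f"ages outside fitted range [{self.age_min}, {self.age_max}]"
            )
        return ages

    def params_at(self, ages, check_range: bool = True) -> dict:
        ages = self._check_ages(ages) if check_range else np.atleast_1d(np.asarray(ages))
        u = age_transform(ages)
        return {name: curve.value(u) for name, curve in self.curves.items()}

    def predict_percentiles(self, ages, probs=None) -> PercentileTable:
        probs = tuple(probs) if probs is not None else None
        from .core_io import DEFAULT_PROBS

        probs = probs or DEFAULT_PROBS
        ages = self._check_ages(ages)
        th = self.params_at(ages)
        tau = th.get("tau")
        values = np.empty((len(ages), len(probs)))
        for j, p in enumerate(probs):
            values[:, j] = families.quantile(
                p, th["mu"], th["sigma"], th["lam"], family=self.family, tau=tau
            )
        return PercentileTable(ages=ages, probs=probs, values=values)

    def value_to_zscore(self, y, ages):
        """z = Phi^-1(F(y | theta(age))); +/-inf where F hits 0 or 1 to
        machine precision (censored z)."""
        ages = self._check_ages(ages)
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise ValidationError("z-scores are defined for positive values only")
        th = self.params_at(ages)
        F = families.cdf(y, th["mu"], th["sigma"], th["lam"],
                         family=self.family, tau=th.get("tau"))
        with np.errstate(divide="ignore"):
            z = ndtri(F)
        out = np.where(F <= 0.0, -np.inf, np.where(F >= 1.0, np.inf, z))
        return float(out.ravel()[0]) if out.size == 1 else out

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format": "refcurve-continuous-model",
            "version": 1,
            "family": self.family,
            "age_transform": "log(age_days + 1)",
            "age_min": int(self.age_min),
            "age_max": int(self.age_max),
            "loglik": self.loglik,
            "bic": self.bic,
            "n_eff": self.n_eff,
            "analyte_label": self.analyte_label,
            "unit_label": self.unit_label,
            "curves": {
                name: {
                    "link": c.link,
                    "knots": c.knots.tolist(),
                    "coef": c.coef.tolist(),
                    "penalty": c.penalty,
                    "edf": c.edf,
                }
                for name, c in self.curves.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ContinuousModel":
        d = json.loads(text)
        if d.get("format") != "refcurve-continuous-model":
            raise ValidationError("not a serialized continuous model")
        curves = {
            name: ParamCurve(
                name=name,
                link=c["link"],
                knots=np.asarray(c["knots"], dtype=float),
                coef=np.asarray(c["coef"], dtype=float),
                penalty=float(c["penalty"]),
                edf=float(c["edf"]),
            )
            for name, c in d["curves"].items()
        }
        return cls(
            family=d["family"], curves=curves, age_min=d["age_min"],
            age_max=d["age_max"], loglik=d["loglik"], bic=d["bic"],
            n_eff=d["n_eff"], analyte_label=d.get("analyte_label", "analyte"),
            unit_label=d.get("unit_label", "a.u."),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ContinuousModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

_FD_ETA = 1e-4   # step for eta-space score differences
_LAM_TINY = 1e-12
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class _FitProblem:
    """Weighted penalized likelihood over concatenated coefficient blocks.

    Parameter curves are functions of transformed age only, and ages are
    integer days, so every age-dependent quantity (linear predictors, the
    positive-support truncation constant, tau-dependent normalization
    terms) is evaluated on the set of unique ages and gathered to
    observations; per-observation work reduces to the z-transform and the
    z-density kernel.  Scores with respect to each linear predictor are
    central eta-space differences, aggregated back to coefficient space
    through the unique-age design matrix.
    """

    def __init__(self, y, u, w, family, knots, penalties):
        self.y = np.asarray(y, dtype=float)
        self.logy = np.log(self.y)
        self.w = np.asarray(w, dtype=float)
        self.family = family
        self.param_names = FAMILY_PARAMS[family]
        self._knots = knots
        self.uq, self.idx = np.unique(np.asarray(u, dtype=float), return_inverse=True)
        self.m = len(self.uq)
        self.Bu = design_matrix(self.uq, knots)
        self.K = self.Bu.shape[1]
        self.DtD = _difference_penalty(self.K)
        self.penalties = dict(penalties)
        self.n_eff = max(float(np.sum(self.w)), 2.0)

    # -- parameter plumbing -----------------------------------------------
    def split(self, theta):
        return {
            name: theta[i * self.K:(i + 1) * self.K]
            for i, name in enumerate(self.param_names)
        }

    def concat(self, blocks):
        return np.concatenate([blocks[name] for name in self.param_names])

    def etas_u(self, theta):
        """Per-curve linear predictors on the unique-age grid.

        The tau predictor is clipped to a tighter box: beyond tau ~ 3000 the
        kurtosis families are numerically indistinguishable from their
        normal-kernel limit, and an unbounded predictor lets the optimizer
        wander along a flat likelihood ridge.
        """
        blocks = self.split(theta)
        return {
            name: np.clip(
                self.Bu @ blocks[name],
                -(_TAU_ETA_CLIP if name == "tau" else _ETA_CLIP),
                _TAU_ETA_CLIP if name == "tau" else _ETA_CLIP,
            )
            for name in self.param_names
        }

    def params_from(self, theta):
        return {
            name: _apply_link(eta, LINKS[name])[self.idx]
            for name, eta in self.etas_u(theta).items()
        }

    # -- log-likelihood ----------------------------------------------------
    def _lp(self, eu):
        """Per-observation weighted-able log density from unique-age etas."""
        idx = self.idx
        em = eu["mu"][idx]
        sigma_u = np.exp(eu["sigma"])
        lam_u = eu["lam"]
        lam = lam_u[idx]
        sigma = sigma_u[idx]
        logr = self.logy - em
        nz = np.abs(lam) > _LAM_TINY
        lam_safe = np.where(nz, lam, 1.0)
        with np.errstate(over="ignore"):
            z = np.where(nz, np.expm1(lam * logr) / (lam_safe * sigma), logr / sigma)
        jac = (lam - 1.0) * self.logy - lam * em - eu["sigma"][idx]

        al_u = np.abs(lam_u)
        lim_u = 1.0 / (sigma_u * np.maximum(al_u, _LAM_TINY))
        if self.family == "BCCG":
            zlp = -0.5 * z * z - _LOG_SQRT_2PI
            C_u = special.ndtr(lim_u)
        elif self.family == "BCT":
            tau_u = np.exp(eu["tau"])
            const_u = (
                special.gammaln((tau_u + 1.0) / 2.0)
                - special.gammaln(tau_u / 2.0)
                - 0.5 * np.log(tau_u * np.pi)
            )
            tau = tau_u[idx]
            zlp = const_u[idx] - (tau + 1.0) / 2.0 * np.log1p(z * z / tau)
            C_u = special.stdtr(tau_u, lim_u)
        else:  # BCPE
            tau_u = np.exp(eu["tau"])
            log_c_u = 0.5 * (
                -2.0 / tau_u * np.log(2.0)
                + special.gammaln(1.0 / tau_u)
                - special.gammaln(3.0 / tau_u)
            )
            const_u = (
                np.log(tau_u)
                - log_c_u
                - (1.0 + 1.0 / tau_u) * np.log(2.0)
                - special.gammaln(1.0 / tau_u)
            )
            tau = tau_u[idx]
            az = np.abs(z)
            with np.errstate(divide="ignore"):
                texp = tau * (np.log(az) - log_c_u[idx])
            core = 0.5 * np.exp(np.minimum(texp, 700.0))
            core = np.where(az == 0, 0.0, core)
            zlp = const_u[idx] - core
            # PE cdf of the truncation limit
            with np.errstate(divide="ignore"):
                tl = tau_u * (np.log(lim_u) - log_c_u)
            C_u = 0.5 * (1.0 + special.gammainc(
                1.0 / tau_u, 0.5 * np.exp(np.minimum(tl, 700.0))
            ))
        logC_u = np.where(al_u < _LAM_TINY, 0.0, np.log(np.clip(C_u, 1e-300, 1.0)))
        return jac + zlp - logC_u[idx]

    def penalty_value(self, blocks):
        return 0.5 * sum(
            self.penalties[name] * blocks[name] @ self.DtD @ blocks[name]
            for name in self.param_names
        )

    def value_and_grad(self, theta):
        blocks = self.split(theta)
        eu = self.etas_u(theta)
        lp = self._lp(eu)
        if not np.all(np.isfinite(lp)):
            return 1e12, np.zeros_like(theta)
        f = -float(self.w @ lp) + self.penalty_value(blocks)
        grads = []
        for name in self.param_names:
            up = dict(eu)
            dn = dict(eu)
            up[name] = eu[name] + _FD_ETA
            dn[name] = eu[name] - _FD_ETA
            dlp = (self._lp(up) - self._lp(dn)) / (2.0 * _FD_ETA)
            score_u = np.bincount(self.idx, weights=self.w * dlp, minlength=self.m)
            g = -self.Bu.T @ score_u + self.penalties[name] * (self.DtD @ blocks[name])
            grads.append(g)
        return f, np.concatenate(grads)

    # -- effective dimension / BIC ----------------------------------------
    def curvature_weights(self, theta, name, delta=1e-3):
        """Unique-age aggregate of w_i * (-d2 logf / d eta_k^2), by central
        second differences in eta space."""
        eu = self.etas_u(theta)
        lp0 = self._lp(eu)
        up = dict(eu)
        dn = dict(eu)
        up[name] = eu[name] + delta
        dn[name] = eu[name] - delta
        d2 = (self._lp(up) - 2.0 * lp0 + self._lp(dn)) / delta**2
        h = np.bincount(self.idx, weights=self.w * (-d2), minlength=self.m)
        return np.maximum(h, 0.0)

    def edf(self, theta, name):
        h = self.curvature_weights(theta, name)
        M = self.Bu.T @ (self.Bu * h[:, None])
        A = M + self.penalties[name] * self.DtD + 1e-10 * np.eye(self.K)
        try:
            return float(np.trace(np.linalg.solve(A, M)))
        except np.linalg.LinAlgError:
            return float(self.K)

    def weighted_loglik(self, theta):
        return float(self.w @ self._lp(self.etas_u(theta)))

    def bic(self, theta):
        edf_total = sum(self.edf(theta, name) for name in self.param_names)
        return -2.0 * self.weighted_loglik(theta) + edf_total * np.log(self.n_eff), edf_total


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    if cw[-1] <= 0:
        return float(np.quantile(x, q))
    return float(np.interp(q * cw[-1], cw, x[order]))


def _initial_theta(problem: _FitProblem, y, u, w, family) -> np.ndarray:
    """Running weighted median / spread curves as starting values."""
    n = len(y)
    nb = int(np.clip(n // 150, 8, 40))
    edges = np.quantile(u, np.linspace(0, 1, nb + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        edges = np.array([u.min(), u.max() + 1e-9])
    mids, med, spread = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (u >= lo) & (u <= hi)
        if np.sum(w[m]) <= 0 or np.sum(m) < 5:
            continue
        mids.append(0.5 * (lo + hi))
        q50 = _weighted_quantile(y[m], w[m], 0.5)
        q25 = _weighted_quantile(y[m], w[m], 0.25)
        q75 = _weighted_quantile(y[m], w[m], 0.75)
        med.append(max(q50, 1e-12))
        spread.append((np.log(max(q75, 1e-12)) - np.log(max(q25, 1e-12))) / 1.349)
    mids = np.asarray(mids)
    med = np.asarray(med)
    spread = np.clip(np.asarray(spread), 5e-3, 2.0)

    Bc = design_matrix(mids, problem._knots)
    ridge = Bc.T @ Bc + 1.0 * problem.DtD + 1e-8 * np.eye(problem.K)

    def lsq(target):
        return np.linalg.solve(ridge, Bc.T @ target)

    c_mu = lsq(np.log(med))
    c_sigma = lsq(np.log(spread))

    # skewness-guided flat start for lam
    wm = np.average(y, weights=np.maximum(w, 1e-12))
    sd = np.sqrt(np.average((y - wm) ** 2, weights=np.maximum(w, 1e-12)))
    skew = np.average(((y - wm) / max(sd, 1e-12)) ** 3, weights=np.maximum(w, 1e-12))
    lam0 = 0.0 if skew > 2.0 else 1.0
    c_lam = np.full(problem.K, lam0)

    blocks = {"mu": c_mu, "sigma": c_sigma, "lam": c_lam}
    if "tau" in problem.param_names:
        tau0 = 2.0 if family == "BCPE" else 10.0
        blocks["tau"] = np.full(problem.K, np.log(tau0))
    return problem.concat(blocks)


def _minimize(problem: _FitProblem, theta0: np.ndarray, rng, max_iter=400,
              n_restarts=2, ftol=1e-10):
    theta = theta0
    for attempt in range(n_restarts + 1):
        res = optimize.minimize(
            problem.value_and_grad, theta, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": ftol, "gtol": 1e-6},
        )
        if np.isfinite(res.fun) and res.fun < 1e11:
            return res.x, float(res.fun)
        logger.warning("optimizer restart %d after failure (%s)", attempt + 1, res.message)
        theta = theta0 + rng.normal(0.0, 0.01, size=theta0.shape)
    raise FittingError(f"penalized likelihood optimization failed: {res.message}")


def fit_weighted_gamlss(
    ages,
    values,
    weights,
    family: str = "BCCG",
    config: PipelineConfig | None = None,
    penalties: dict | None = None,
    select_smoothing: bool | None = None,
    select_curves: tuple | None = None,
    init_theta: np.ndarray | None = None,
    n_interior: int = N_INTERIOR_KNOTS,
    penalty_grid=PENALTY_GRID,
    analyte_label: str = "analyte",
    unit_label: str = "a.u.",
) -> ContinuousModel:
    """Fit one family's smooth parameter curves to weighted data.

    ``penalties`` fixes the per-curve smoothing strengths; otherwise they
    are selected curve-by-curve over ``penalty_grid`` by BIC (one pass,
    warm-started).  Randomness (jittered restarts only) is seeded from the
    config.
    """
    if family not in FAMILY_PARAMS:
        raise ValidationError(f"unknown family {family!r}")
    config = config or PipelineConfig()
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (len(ages) == len(y) == len(w)):
        raise ValidationError("ages, values and weights must align")
    if np.any((w < 0) | (w > 1)):
        raise ValidationError("weights must lie in [0, 1]")
    if np.any(y <= 0):
        raise ValidationError("values must be positive")
    if int(np.sum(w > 0)) < MIN_WEIGHTED_POINTS:
        raise FittingError(
            f"need >= {MIN_WEIGHTED_POINTS} points with positive weight, "
            f"got {int(np.sum(w > 0))}"
        )
    u = age_transform(ages)
    knots = make_knots(float(u.min()), float(u.max()), n_interior)
    names = FAMILY_PARAMS[family]
    pens = {name: DEFAULT_PENALTY for name in names}
    if penalties:
        pens.update(penalties)
    problem = _FitProblem(y, u, w, family, knots, pens)
    rng = np.random.default_rng(config.rng_seed)

    theta0 = init_theta if init_theta is not None else _initial_theta(problem, y, u, w, family)
    theta, _ = _minimize(problem, theta0, rng)

    if select_smoothing is None:
        select_smoothing = penalties is None or select_curves is not None
    if select_smoothing and problem.K > 2:
        best_bic, _ = problem.bic(theta)
        for name in (select_curves if select_curves is not None else names):
            cur_pen = problem.penalties[name]
            best_pen, best_theta = cur_pen, theta
            for g in penalty_grid:
                if g == cur_pen:
                    continue
                problem.penalties[name] = g
                try:
                    cand_theta, _ = _minimize(problem, theta, rng, max_iter=150,
                                              n_restarts=0, ftol=1e-9)
                except FittingError:
                    continue
                cand_bic, _ = problem.bic(cand_theta)
                if cand_bic < best_bic - 1e-9:
                    best_bic, best_pen, best_theta = cand_bic, g, cand_theta
            problem.penalties[name] = best_pen
            theta = best_theta
        theta, _ = _minimize(problem, theta, rng)

    loglik = problem.weighted_loglik(theta)
    bic, edf_total = problem.bic(theta)
    blocks = problem.split(theta)
    curves = {
        name: ParamCurve(
            name=name, link=LINKS[name], knots=knots,
            coef=np.array(blocks[name]), penalty=problem.penalties[name],
            edf=problem.edf(theta, name),
        )
        for name in names
    }
    model = ContinuousModel(
        family=family, curves=curves,
        age_min=int(np.min(ages)), age_max=int(np.max(ages)),
        loglik=loglik, bic=float(bic), n_eff=float(np.sum(w)),
        analyte_label=analyte_label, unit_label=unit_label,
    )
    logger.info(
        "fitted %s: loglik = %.2f, edf = %.1f, BIC = %.2f", family, loglik,
        edf_total, bic,
    )
    return model


def select_best_family(models) -> ContinuousModel:
    """Minimal-BIC model; ties break to fewer effective df, then family
    order BCCG < BCPE < BCT."""
    models = [m for m in models if m is not None]
    if not models:
        raise PipelineError("all family fits failed; no continuous model available")
    return min(
        models,
        key=lambda m: (round(m.bic, 9), round(m.total_edf, 9), FAMILY_ORDER.index(m.family)),
    )


def predict_percentiles(model: ContinuousModel, ages, probs=None) -> PercentileTable:
    return model.predict_percentiles(ages, probs)


def value_to_zscore(model: ContinuousModel, y, ages):
    return model.value_to_zscore(y, ages)
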