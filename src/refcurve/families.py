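"""Box-Cox distribution families for quantile-curve modelling.

The three families used for age-dependent percentile charts are the Box-Cox
Cole-Green distribution (BCCG, the classical LMS growth-chart model), the
Box-Cox power exponential (BCPE) and the Box-Cox t (BCT).  All three model a
positive response ``y`` through the shifted power transform

    z = ((y / mu)**lam - 1) / (lam * sigma)        (lam != 0)
    z = log(y / mu) / sigma                        (lam == 0)

where ``mu`` is the (median) location, ``sigma`` a coefficient-of-variation
like scale, and ``lam`` the skewness power.  The transformed variable ``z``
follows a standard normal (BCCG), a standardized power exponential with
kurtosis parameter ``tau`` (BCPE; ``tau = 2`` recovers BCCG), or a Student-t
with ``tau`` degrees of freedom (BCT; ``tau -> inf`` recovers BCCG).

Because ``y > 0`` truncates the range of ``z``, densities are renormalized by
the positive-support mass ``C = F_Z(1 / (sigma * |lam|))`` so that every
density integrates to one on (0, inf).  The same constant enters the CDF and
quantile function, so ``cdf(quantile(p)) = p`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

FAMILIES = ("BCCG", "BCPE", "BCT")

#: parameter curves each family requires, in fitting order
FAMILY_PARAMS = {
    "BCCG": ("mu", "sigma", "lam"),
    "BCPE": ("mu", "sigma", "lam", "tau"),
    "BCT": ("mu", "sigma", "lam", "tau"),
}

_LOG2 = np.log(2.0)
_LAM_TINY = 1e-12  # |lam| below this is treated as the log-limit


@dataclass(frozen=True)
class FamilyParams:
    """One age-slice of distribution parameters.

    ``tau`` is the kurtosis parameter (power for BCPE, degrees of freedom for
    BCT) and must be ``None`` for BCCG.
    """

    mu: float
    sigma: float
    lam: float
    tau: float | None = None

    def __post_init__(self) -> None:
        if not (self.mu > 0 and np.isfinite(self.mu)):
            raise ValueError(f"mu must be positive and finite, got {self.mu}")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.tau is not None and not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


def _check_family(family: str, tau) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if family != "BCCG" and tau is None:
        raise ValueError(f"{family} requires a tau parameter")


def bc_transform(y, mu, sigma, lam):
    """The Box-Cox z-transform of a positive value; continuous in lam at 0."""
    y, mu, sigma, lam = np.broadcast_arrays(
        *map(np.asarray, (y, mu, sigma, lam)), subok=False
    )
    if np.any(np.asarray(y) <= 0):
        raise ValueError("Box-Cox transform requires y > 0")
    r = np.log(y / mu)
    lam_safe = np.where(np.abs(lam) < _LAM_TINY, 1.0, lam)
    with np.errstate(over="ignore"):
        z_pow = np.expm1(lam_safe * r) / (lam_safe * sigma)
    z_log = r / sigma
    return np.where(np.abs(lam) < _LAM_TINY, z_log, z_pow)


# ---------------------------------------------------------------------------
# z-scale distributions
# ---------------------------------------------------------------------------

def _pe_log_c(tau):
    # c**2 = 2**(-2/tau) * Gamma(1/tau) / Gamma(3/tau): Var(Z) = 1
    return 0.5 * (-2.0 / tau * _LOG2 + special.gammaln(1.0 / tau) - special.gammaln(3.0 / tau))


def _pe_logpdf(z, tau):
    log_c = _pe_log_c(tau)
    # 0.5*|z/c|**tau computed in log space to avoid overflow at large tau
    az = np.abs(z)
    with np.errstate(divide="ignore"):
        t = tau * (np.log(az) - log_c)
    t = np.where(az == 0, -np.inf, t)
    core = 0.5 * np.exp(np.minimum(t, 700.0))
    return (
        np.log(tau)
        - log_c
        - (1.0 + 1.0 / tau) * _LOG2
        - special.gammaln(1.0 / tau)
        - core
    )


def _pe_cdf(z, tau):
    log_c = _pe_log_c(tau)
    az = np.abs(z)
    with np.errstate(divide="ignore"):
        t = tau * (np.log(az) - log_c)
    u = 0.5 * np.exp(np.minimum(t, 700.0))
    g = special.gammainc(1.0 / tau, u)
    g = np.where(az == 0, 0.0, g)
    return 0.5 * (1.0 + np.sign(z) * g)


def _pe_ppf(q, tau):
    log_c = _pe_log_c(tau)
    s = np.sign(q - 0.5)
    g = special.gammaincinv(1.0 / tau, np.abs(2.0 * q - 1.0))
    return s * np.exp(log_c) * (2.0 * g) ** (1.0 / tau)


def _t_logpdf(z, df):
    return (
        special.gammaln((df + 1.0) / 2.0)
        - special.gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - (df + 1.0) / 2.0 * np.log1p(z * z / df)
    )


def _z_logpdf(z, family, tau):
    if family == "BCCG":
        return -0.5 * z * z - 0.5 * np.log(2.0 * np.pi)
    if family == "BCPE":
        return _pe_logpdf(z, tau)
    return _t_logpdf(z, tau)


def _z_cdf(z, family, tau):
    if family == "BCCG":
        return special.ndtr(z)
    if family == "BCPE":
        return _pe_cdf(z, tau)
    return special.stdtr(tau, z)


def _z_ppf(q, family, tau):
    if family == "BCCG":
        return special.ndtri(q)
    if family == "BCPE":
        return _pe_ppf(q, tau)
    return special.stdtrit(np.asarray(tau, dtype=float), q)


def _log_trunc_const(sigma, lam, family, tau):
    """log C with C = F_Z(1/(sigma*|lam|)); C = 1 in the lam = 0 limit."""
    lam = np.asarray(lam, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    al = np.abs(lam)
    lim = 1.0 / (sigma * np.maximum(al, _LAM_TINY))
    C = _z_cdf(lim, family, tau)
    logC = np.log(np.clip(C, 1e-300, 1.0))
    return np.where(al < _LAM_TINY, 0.0, logC)


# ---------------------------------------------------------------------------
# public family API
# ---------------------------------------------------------------------------

def log_density(y, mu, sigma, lam, family="BCCG", tau=None):
    """Log density of y > 0 under the given Box-Cox family.

    All arguments broadcast; ``tau`` is ignored for BCCG.
    """
    _check_family(family, tau)
    y, mu, sigma, lam = np.broadcast_arrays(
        *map(lambda a: np.asarray(a, dtype=float), (y, mu, sigma, lam))
    )
    z = bc_transform(y, mu, sigma, lam)
    jac = (lam - 1.0) * np.log(y) - lam * np.log(mu) - np.log(sigma)
    return jac + _z_logpdf(z, family, tau) - _log_trunc_const(sigma, lam, family, tau)


def density(y, mu, sigma, lam, family="BCCG", tau=None):
    return np.exp(log_density(y, mu, sigma, lam, family=family, tau=tau))


def cdf(y, mu, sigma, lam, family="BCCG", tau=None):
    """Distribution function on (0, inf), truncation-corrected."""
    _check_family(family, tau)
    y, mu, sigma, lam = np.broadcast_arrays(
        *map(lambda a: np.asarray(a, dtype=float), (y, mu, sigma, lam))
    )
    z = bc_transform(y, mu, sigma, lam)
    Fz = _z_cdf(z, family, tau)
    C = np.exp(_log_trunc_const(sigma, lam, family, tau))
    # lam > 0: z is bounded below at -1/(sigma*lam); mass below is 1 - C
    F_pos = (Fz - (1.0 - C)) / C
    F_neg = Fz / C
    F = np.where(lam > _LAM_TINY, F_pos, F_neg)
    return np.clip(F, 0.0, 1.0)


def quantile(p, mu, sigma, lam, family="BCCG", tau=None):
    """Quantile function; exact inverse of :func:`cdf` on (0, 1)."""
    _check_family(family, tau)
    p, mu, sigma, lam = np.broadcast_arrays(
        *map(lambda a: np.asarray(a, dtype=float), (p, mu, sigma, lam))
    )
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    C = np.exp(_log_trunc_const(sigma, lam, family, tau))
    q_adj = np.where(lam > _LAM_TINY, p * C + (1.0 - C), p * C)
    q_adj = np.clip(q_adj, 1e-300, 1.0 - 1e-16)
    zp = _z_ppf(q_adj, family, tau)
    lam_safe = np.where(np.abs(lam) < _LAM_TINY, 1.0, lam)
    arg = lam_safe * sigma * zp
    if np.any((np.abs(lam) >= _LAM_TINY) & (arg <= -1.0)):
        raise ValueError("quantile undefined: Box-Cox argument non-positive")
    # exp(log1p(.)/lam) rather than (1+.)**(1/lam): full precision as lam -> 0
    with np.errstate(divide="ignore", invalid="ignore"):
        y_pow = mu * np.exp(np.log1p(np.maximum(arg, -1.0 + 1e-300)) / lam_safe)
    y_log = mu * np.exp(sigma * zp)
    return np.where(np.abs(lam) < _LAM_TINY, y_log, y_pow)


def sample(n, mu, sigma, lam, family="BCCG", tau=None, rng=None):
    """Draw n values by inverse-CDF sampling (handles truncation exactly)."""
    rng = np.random.default_rng(rng)
    u = rng.uniform(1e-12, 1.0 - 1e-12, size=n)
    return quantile(u, mu, sigma, lam, family=family, tau=tau)
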