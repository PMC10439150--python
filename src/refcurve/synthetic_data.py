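"""Seeded synthetic routine-measurement datasets with known truth.

Real routine laboratory datasets are a mixture of non-pathological samples
from age-dependent skewed distributions and a pathological admixture, with
repeated samples per subject and a strong overrepresentation of neonates and
infants.  This module generates such datasets from closed-form truth curves
so that every pipeline stage can be evaluated against a known answer.

Three named scenarios are styled after common pediatric analytes:

* ``alp_like``  - alkaline-phosphatase-like: a right-skewed distribution
  with an infancy peak around day 100 and a second pubertal peak, U/L.
* ``crea_like`` - creatinine-like: rapid neonatal fall then a slow rise to
  adulthood, mg/dL.
* ``hb_like``   - hemoglobin-like: brief rise after birth, fall to ~day 50,
  then a slow rise with a pubertal step, g/dL.

The shapes are qualitative emulations of the published dynamics of these
analytes; the parameter values are this package's own and are not estimates
of any real population.  Pathological contamination is one-sided: a
multiplicative shift of the location (default x1.8) with inflated scale,
mimicking the typical high-side pathological pattern an indirect method must
resist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from . import families
from .core_io import MeasurementSet, PercentileTable, ValidationError

DEFAULT_SAMPLES_PER_SUBJECT = ((1, 0.60), (2, 0.25), (3, 0.10), (5, 0.05))


@dataclass
class Scenario:
    """A synthetic-data scenario with closed-form truth curves.

    ``lam_fn``, ``mu_fn``, ``sigma_fn`` (and optional ``tau_fn``) map an age
    in days to the distribution parameters of the clean (non-pathological)
    component.  ``pathological_fraction`` is a constant or a function of
    age, bounded by 0.4; pathological values are drawn from the same family
    with ``mu * pathological_shift`` and ``sigma * pathological_sigma_inflation``.
    Ages come from a mixture of a log-uniform (neonatal overrepresentation)
    and a uniform component.
    """

    name: str
    mu_fn: Callable
    sigma_fn: Callable
    lam_fn: Callable
    n_total: int
    seed: int
    family: str = "BCCG"
    tau_fn: Callable | None = None
    pathological_fraction: float | Callable = 0.10
    pathological_shift: float = 1.8
    pathological_sigma_inflation: float = 1.5
    max_age_days: int = 6570
    log_uniform_weight: float = 0.7
    samples_per_subject: tuple = DEFAULT_SAMPLES_PER_SUBJECT
    analyte_label: str = "analyte"
    unit_label: str = "a.u."

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValidationError("n_total must be >= 1")
        if not 0 <= self.log_uniform_weight <= 1:
            raise ValidationError("log_uniform_weight must lie in [0, 1]")
        if self.family != "BCCG" and self.tau_fn is None:
            raise ValidationError(f"{self.family} scenario needs tau_fn")
        probs = np.array([p for _, p in self.samples_per_subject], dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValidationError("samples_per_subject probabilities must sum to 1")
        check_ages = np.linspace(0, self.max_age_days, 200)
        mu = np.asarray(self.mu_fn(check_ages), dtype=float)
        sg = np.asarray(self.sigma_fn(check_ages), dtype=float)
        if np.any(mu <= 0) or np.any(sg <= 0):
            raise ValidationError("mu and sigma truth curves must be positive everywhere")
        pf = self.path_fraction_at(check_ages)
        if np.any((pf < 0) | (pf > 0.4)):
            raise ValidationError("pathological_fraction must lie in [0, 0.4]")

    def path_fraction_at(self, ages) -> np.ndarray:
        if callable(self.pathological_fraction):
            return np.asarray(self.pathological_fraction(np.asarray(ages)), dtype=float)
        return np.full(np.shape(ages), float(self.pathological_fraction))

    def params_at(self, ages) -> dict:
        ages = np.asarray(ages, dtype=float)
        out = {
            "mu": np.asarray(self.mu_fn(ages), dtype=float),
            "sigma": np.asarray(self.sigma_fn(ages), dtype=float),
            "lam": np.asarray(self.lam_fn(ages), dtype=float),
        }
        if self.tau_fn is not None:
            out["tau"] = np.asarray(self.tau_fn(ages), dtype=float)
        return out


def _bump(u, center_u, width_u):
    return np.exp(-0.5 * ((u - center_u) / width_u) ** 2)


def alp_like(n_total: int = 50_000, seed: int = 0, **overrides) -> Scenario:
    """Alkaline-phosphatase-like scenario (U/L): infancy peak near day 100,
    pubertal peak near 13 years, right-skew (lam < 1)."""

    def mu(a):
        u = np.log(np.asarray(a, dtype=float) + 1.0)
        return 120.0 + 210.0 * _bump(u, np.log(101.0), 0.9) + 120.0 * _bump(u, np.log(4800.0), 0.25)

    def sigma(a):
        u = np.log(np.asarray(a, dtype=float) + 1.0)
        return 0.16 + 0.04 * _bump(u, np.log(101.0), 1.2)

    def lam(a):
        return np.full(np.shape(a), 0.35)

    kw = dict(
        name="alp_like", mu_fn=mu, sigma_fn=sigma, lam_fn=lam,
        n_total=n_total, seed=seed, analyte_label="ALP-like", unit_label="U/L",
    )
    kw.update(overrides)
    return Scenario(**kw)


def crea_like(n_total: int = 50_000, seed: int = 0, **overrides) -> Scenario:
    """Creatinine-like scenario (mg/dL): neonatal fall, slow rise to 18 y."""

    def mu(a):
        a = np.asarray(a, dtype=float)
        return 0.23 + 0.62 * np.exp(-a / 45.0) + 0.50 * (a / 6570.0) ** 1.4

    def sigma(a):
        return np.full(np.shape(a), 0.14)

    def lam(a):
        return np.full(np.shape(a), 0.30)

    kw = dict(
        name="crea_like", mu_fn=mu, sigma_fn=sigma, lam_fn=lam,
        n_total=n_total, seed=seed, analyte_label="CREA-like", unit_label="mg/dL",
    )
    kw.update(overrides)
    return Scenario(**kw)


def hb_like(n_total: int = 50_000, seed: int = 0, **overrides) -> Scenario:
    """Hemoglobin-like scenario (g/dL): rise after birth, fall to ~day 50,
    slow recovery, pubertal step."""

    def mu(a):
        a = np.asarray(a, dtype=float)
        u = np.log(a + 1.0)
        neonatal = 7.2 * _bump(u, np.log(4.0), 1.1) * np.exp(-a / 60.0)
        puberty = 1.6 / (1.0 + np.exp(-(a - 4600.0) / 350.0))
        return 10.9 + neonatal + 0.9 * (a / 6570.0) + puberty

    def sigma(a):
        return np.full(np.shape(a), 0.075)

    def lam(a):
        return np.full(np.shape(a), 1.2)

    kw = dict(
        name="hb_like", mu_fn=mu, sigma_fn=sigma, lam_fn=lam,
        n_total=n_total, seed=seed, analyte_label="HB-like", unit_label="g/dL",
    )
    kw.update(overrides)
    return Scenario(**kw)


SCENARIOS = {"alp_like": alp_like, "crea_like": crea_like, "hb_like": hb_like}


def sample_ages(n: int, scenario: Scenario, rng: np.random.Generator) -> np.ndarray:
    """Ages in days: log-uniform/uniform mixture over [0, max_age_days]
    emulating the neonatal overrepresentation of routine datasets."""
    take_log = rng.random(n) < scenario.log_uniform_weight
    hi = scenario.max_age_days
    ages = np.empty(n)
    n_log = int(take_log.sum())
    ages[take_log] = np.exp(rng.uniform(0.0, np.log(hi + 1.0), n_log)) - 1.0
    ages[~take_log] = rng.uniform(0.0, hi + 1.0, n - n_log)
    return np.minimum(np.floor(ages).astype(np.int64), hi)


def generate_dataset(scenario: Scenario) -> tuple[MeasurementSet, np.ndarray]:
    """Draw a full synthetic dataset; returns the measurements and a boolean
    array marking pathological rows (ground truth).  Reproducible from
    ``scenario.seed``."""
    rng = np.random.default_rng(scenario.seed)
    counts = np.array([k for k, _ in scenario.samples_per_subject])
    probs = np.array([p for _, p in scenario.samples_per_subject], dtype=float)

    subj_ids: list[str] = []
    ages_list: list[np.ndarray] = []
    total = 0
    si = 0
    mean_k = float(counts @ probs)
    while total < scenario.n_total:
        batch = max(64, int((scenario.n_total - total) / mean_k * 1.1))
        ks = rng.choice(counts, size=batch, p=probs)
        base_ages = sample_ages(batch, scenario, rng)
        for k, base in zip(ks, base_ages):
            k = int(min(k, scenario.n_total - total))
            if k <= 0:
                break
            w = max(3, int(0.08 * base))
            offs = np.concatenate([[0], rng.integers(-w, w + 1, size=k - 1)])
            a = np.clip(base + offs, 0, scenario.max_age_days)
            ages_list.append(a)
            subj_ids.extend([f"S{si:07d}"] * k)
            si += 1
            total += k
    ages = np.concatenate(ages_list).astype(np.int64)

    th = scenario.params_at(ages)
    pf = scenario.path_fraction_at(ages)
    is_path = rng.random(len(ages)) < pf
    mu = np.where(is_path, th["mu"] * scenario.pathological_shift, th["mu"])
    sigma = np.where(
        is_path, th["sigma"] * scenario.pathological_sigma_inflation, th["sigma"]
    )
    tau = th.get("tau")
    u01 = rng.uniform(1e-12, 1.0 - 1e-12, len(ages))
    values = families.quantile(
        u01, mu, sigma, th["lam"], family=scenario.family, tau=tau
    )

    df = pd.DataFrame(
        {
            "value": values,
            "age_days": ages,
            "sex": "A",
            "subject_id": np.asarray(subj_ids),
        }
    )
    ms = MeasurementSet(df, analyte_label=scenario.analyte_label,
                        unit_label=scenario.unit_label)
    return ms, is_path


def truth_percentiles(scenario: Scenario, ages, probs) -> PercentileTable:
    """Closed-form percentiles of the clean component at the truth curves;
    the recovery oracle for every pipeline test."""
    ages = np.asarray(ages)
    th = scenario.params_at(ages)
    probs = tuple(probs)
    values = np.empty((len(ages), len(probs)))
    for j, p in enumerate(probs):
        values[:, j] = families.quantile(
            p, th["mu"], th["sigma"], th["lam"], family=scenario.family,
            tau=th.get("tau"),
        )
    return PercentileTable(ages=ages, probs=probs, values=values)
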