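"""Probability-of-being-non-pathological weights (step 3 of the pipeline).

For each age group the fitted non-pathological model supplies a density
``D_np(conc) = np_fraction * bcn_pdf(conc)``; the raw data of the group
supply a kernel-density estimate ``D_total(conc)``.  The weight of a
concentration is

    P(conc, a) = min(1, max(0, D_np(conc, a) / D_total(conc, a)))

with slight Gaussian smoothing applied to the concentration-dependent ratio
before clipping.  Because groups overlap, each measurement takes its single
weight from the group whose center is nearest its age.  Finally the weight
is divided by the number of samples its subject contributes to the whole
dataset, down-weighting repeatedly sampled subjects:

    P_corr(subject, conc, a) = P(conc, a) / N_subject
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .core_io import MeasurementSet, PipelineError, ValidationError
from .indirect_np import NPModel, bcn_pdf

logger = logging.getLogger(__name__)

GRID_SIZE = 512
SMOOTH_SD_STEPS = 2.0  # Gaussian smoothing sd in grid steps


@dataclass
class WeightedDataset:
    """Measurements with exactly one probability weight each."""

    measurements: MeasurementSet
    p_raw: np.ndarray        # density-ratio weight in [0, 1]
    p_corr: np.ndarray       # weight after repeated-measurement correction
    source_group: np.ndarray  # center day of the assigning group
    n_subject: np.ndarray    # whole-dataset sample count of the row's subject

    def __post_init__(self) -> None:
        n = len(self.measurements)
        for name in ("p_raw", "p_corr", "source_group", "n_subject"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValidationError(f"{name} must align with measurements")
            setattr(self, name, arr)
        if np.any((self.p_raw < 0) | (self.p_raw > 1)):
            raise ValidationError("p_raw must lie in [0, 1]")
        if np.any(self.p_corr > self.p_raw + 1e-15):
            raise ValidationError("correction may not increase a weight")

    def to_frame(self):
        import pandas as pd

        df = self.measurements.to_dataframe()
        df["p_raw"] = self.p_raw
        df["p_corr"] = self.p_corr
        df["source_group"] = self.source_group
        return df


def empirical_density(values, eval_points) -> np.ndarray:
    """Gaussian KDE (Silverman bandwidth) of the group's raw values."""
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 2:
        raise ValidationError("KDE requires >= 2 distinct values")
    kde = gaussian_kde(values, bw_method="silverman")
    return kde(np.asarray(eval_points, dtype=float))


def gaussian_smooth(x: np.ndarray, sd: float, truncate: float = 4.0) -> np.ndarray:
    """Discrete Gaussian smoothing with edge replication.

    The kernel is a normalized Gaussian truncated at ``truncate * sd`` steps;
    the series is padded with its edge values before convolution so the
    output has the input's length.
    """
    x = np.asarray(x, dtype=float)
    r = int(truncate * sd + 0.5)
    if r < 1:
        return x.copy()
    k = np.exp(-0.5 * (np.arange(-r, r + 1) / sd) ** 2)
    k /= k.sum()
    padded = np.concatenate([np.full(r, x[0]), x, np.full(r, x[-1])])
    return np.convolve(padded, k, mode="valid")


def raw_density_ratio(
    values, model: NPModel, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unsmoothed, unclipped ratio D_np / D_total on ``grid`` (0 where
    D_total vanishes), plus D_total itself."""
    d_total = empirical_density(values, grid)
    d_np = model.np_fraction * bcn_pdf(grid, model)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d_total > 0, d_np / d_total, 0.0)
    return ratio, d_total


def density_ratio_weights(
    values,
    model: NPModel,
    at=None,
    grid_size: int = GRID_SIZE,
    smooth_sd: float = SMOOTH_SD_STEPS,
) -> np.ndarray:
    """Density-ratio weights for concentrations ``at`` (default: ``values``).

    The ratio is evaluated on a ``grid_size``-point grid spanning the group's
    data range (extended to cover ``at``), smoothed along concentration with
    a Gaussian kernel of ``smooth_sd`` grid steps, clipped to [0, 1], then
    linearly interpolated to the requested points.
    """
    values = np.asarray(values, dtype=float)
    at = values if at is None else np.asarray(at, dtype=float)
    if np.any(at <= 0):
        raise ValidationError("weights are defined for positive concentrations only")
    lo = min(values.min(), at.min())
    hi = max(values.max(), at.max())
    if not lo < hi:
        hi = lo * (1 + 1e-9) + 1e-12
    grid = np.linspace(lo, hi, grid_size)
    ratio, _ = raw_density_ratio(values, model, grid)
    smoothed = gaussian_smooth(ratio, smooth_sd)
    clipped = np.clip(smoothed, 0.0, 1.0)
    return np.interp(at, grid, clipped)


def assign_single_weight(
    ms: MeasurementSet, groups, models: dict
) -> tuple[np.ndarray, np.ndarray]:
    """One density-ratio weight per measurement from its nearest group center.

    Groups whose indirect fit failed propagate no weights: their
    measurements fall to the next-nearest fitted group (logged).  If no
    group with a model covers a measurement, the pipeline aborts.
    Ties in center distance resolve to the younger center.
    """
    fitted = [g for g in groups if models.get(g.center_day) is not None]
    if not fitted:
        raise PipelineError("no age group has a fitted non-pathological model")
    n_skipped = len(groups) - len(fitted)
    if n_skipped:
        logger.warning("%d groups without fitted models are skipped for weighting", n_skipped)
    centers = np.array([g.center_day for g in fitted])
    order = np.argsort(centers, kind="stable")
    centers = centers[order]
    fitted = [fitted[i] for i in order]

    ages = ms.age_days
    # nearest center with younger-center tie-break: argmin over |age - c|
    pos = np.searchsorted(centers, ages)
    pos_left = np.clip(pos - 1, 0, len(centers) - 1)
    pos_right = np.clip(pos, 0, len(centers) - 1)
    d_left = np.abs(ages - centers[pos_left])
    d_right = np.abs(ages - centers[pos_right])
    choice = np.where(d_left <= d_right, pos_left, pos_right)  # <= : younger wins ties

    p_raw = np.empty(len(ms), dtype=float)
    source = np.empty(len(ms), dtype=np.int64)
    values = ms.values
    for gi, g in enumerate(fitted):
        mask = choice == gi
        if not np.any(mask):
            continue
        model = models[g.center_day]
        member_values = values[g.member_idx]
        p_raw[mask] = density_ratio_weights(member_values, model, at=values[mask])
        source[mask] = g.center_day
    return p_raw, source


def subject_correction(p_raw, subject_ids) -> tuple[np.ndarray, np.ndarray]:
    """Divide each weight by its subject's whole-dataset sample count."""
    p_raw = np.asarray(p_raw, dtype=float)
    subject_ids = np.asarray(subject_ids)
    if len(p_raw) != len(subject_ids):
        raise ValidationError("p_raw and subject_ids must align")
    _, inverse, counts = np.unique(subject_ids, return_inverse=True, return_counts=True)
    n_subject = counts[inverse]
    return p_raw / n_subject, n_subject


def build_weighted_dataset(ms: MeasurementSet, groups, models: dict) -> WeightedDataset:
    """Steps 3a-3c: assign, correct, and package the weights."""
    p_raw, source = assign_single_weight(ms, groups, models)
    p_corr, n_subject = subject_correction(p_raw, ms.subject_id)
    return WeightedDataset(ms, p_raw, p_corr, source, n_subject)
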