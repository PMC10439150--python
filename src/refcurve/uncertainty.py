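"""Bootstrap confidence bands for percentile curves.

The input dataset is resampled with replacement at the measurement level;
the pipeline is rerun on each replicate (subject sample counts for the
repeated-measurement correction are recomputed within the replicate) and
percentiles are predicted on the point estimate's age grid.  Per (age,
percentile) cell the confidence interval is the central ``ci_level`` region
of the replicate values; where the strongly asymmetric bootstrap
distribution leaves the point estimate outside its own band, the band is
expanded to include it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import MeasurementSet, PercentileTable, PipelineConfig, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    """Replicate percentile predictions and the derived central CI."""

    replicate_values: np.ndarray  # [n_success, n_ages, n_probs]
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_requested: int
    n_failed: int

    @property
    def n_success(self) -> int:
        return self.n_requested - self.n_failed


def expand_ci_to_include(ci_lower, ci_upper, point_estimate):
    """Per-cell expansion so the band always contains the point estimate."""
    lo = np.minimum(np.asarray(ci_lower, dtype=float), point_estimate)
    hi = np.maximum(np.asarray(ci_upper, dtype=float), point_estimate)
    return lo, hi


def central_interval(replicates: np.ndarray, ci_level: float):
    """Empirical central interval per cell (linear interpolation between
    order statistics) over the replicate axis (axis 0)."""
    alpha = (1.0 - ci_level) / 2.0
    lo = np.quantile(replicates, alpha, axis=0, method="linear")
    hi = np.quantile(replicates, 1.0 - alpha, axis=0, method="linear")
    return lo, hi


def _resample_indices(dataset, rng, unit: str) -> np.ndarray:
    n = len(dataset)
    if unit == "measurements":
        return rng.integers(0, n, size=n)
    if unit == "subjects":
        subjects = dataset.subject_id
        uniq = np.unique(subjects)
        rows_of = {s: np.flatnonzero(subjects == s) for s in uniq}
        drawn = rng.choice(uniq, size=len(uniq), replace=True)
        return np.concatenate([rows_of[s] for s in drawn])
    raise PipelineError(f"unknown resampling unit {unit!r}")


def bootstrap_percentile_ci(
    dataset: MeasurementSet,
    config: PipelineConfig,
    point_table: PercentileTable,
    point_model=None,
    refit=None,
    resample_unit: str = "measurements",
) -> BootstrapResult:
    """Run ``config.bootstrap_B`` replicate pipelines and form central CIs.

    ``refit`` maps ``(MeasurementSet, PipelineConfig) -> ContinuousModel``;
    by default it is the pipeline's replicate refit conditioned on
    ``point_model`` (which is then required).  ``resample_unit`` is
    ``"measurements"`` (default) or ``"subjects"`` (clustered resampling:
    whole subjects are drawn with replacement).  Replicate RNG streams
    derive from ``(rng_seed, replicate_index)`` so runs are reproducible and
    order-insensitive.  Failed replicates are dropped and counted; more than
    50% failures is fatal.
    """
    if config.bootstrap_B < 2:
        raise PipelineError("bootstrap needs B >= 2")
    if refit is None:
        if point_model is None:
            raise PipelineError("either point_model or refit must be given")
        from .pipeline import refit_replicate

        def refit(ms, cfg):
            return refit_replicate(ms, cfg, point_model)

    B = config.bootstrap_B
    ages = point_table.ages
    probs = point_table.probs
    reps = []
    n_failed = 0
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, b]))
        idx = _resample_indices(dataset, rng, resample_unit)
        try:
            ms_b = dataset.take(idx)
            model_b = refit(ms_b, config)
            lo_a = max(int(ms_b.age_days.min()), int(ages.min()))
            hi_a = min(int(ms_b.age_days.max()), int(ages.max()))
            in_range = (ages >= lo_a) & (ages <= hi_a)
            if not np.all(in_range):
                raise PipelineError(
                    "replicate age range does not cover the prediction grid"
                )
            tab = model_b.predict_percentiles(ages, probs)
            reps.append(tab.values)
        except Exception as exc:  # noqa: BLE001 - replicate failures are counted
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            n_failed += 1
    if n_failed > B / 2:
        raise PipelineError(
            f"{n_failed} of {B} bootstrap replicates failed; aborting"
        )
    replicate_values = np.stack(reps, axis=0)
    lo, hi = central_interval(replicate_values, config.ci_level)
    logger.info("bootstrap: %d/%d replicates succeeded", B - n_failed, B)
    return BootstrapResult(
        replicate_values=replicate_values, ci_lower=lo, ci_upper=hi,
        n_requested=B, n_failed=n_failed,
    )
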