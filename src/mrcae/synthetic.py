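"""Synthetic expression cohorts with planted driver features and survival effects.

The generator emulates the structure the multi-run selection framework is
built to exploit: a small set of *driver* features determines both class
identity (class-specific driver means) and the values of many *dependent*
features (noisy positive linear mixes of the drivers), while the remainder is
pure noise. Because the drivers are known by construction, they serve as the
ground truth for feature-recovery tests. Survival times follow an exponential
hazard that doubles (or scales by any chosen log-ratio) above the median of a
chosen driver, with independent uniform censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .data_io import ClinicalTable, ExpressionMatrix, LabelVector, min_max_normalize


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Defaults are desk-scale study conditions: 500 samples x 200 features with
    10 drivers and 4 balanced classes. ``class_sep`` is the spacing (in units
    of the within-class standard deviation, which is 1) between consecutive
    class means along each driver; ``dependent_fraction`` of the non-driver
    features are noisy mixes of ``mix_sparsity`` randomly chosen drivers;
    ``noise_sd`` is the standard deviation of the additive noise on dependent
    features. At the defaults a dependent feature correlates moderately
    (r ~ 0.5-0.6) with its driving mix, as co-expressed downstream genes do;
    this keeps the planted drivers identifiable as the uniquely cleanest
    representatives of their co-expression clusters.
    """

    n_samples: int = 500
    n_features: int = 200
    n_drivers: int = 10
    n_classes: int = 4
    class_sep: float = 2.0
    dependent_fraction: float = 0.6
    mix_sparsity: int = 3
    noise_sd: float = 2.0
    survival_driver: int | None = 0
    hazard_log_ratio: float = math.log(2.0)
    baseline_hazard: float = 0.01
    censor_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_drivers >= self.n_features:
            raise ValueError("n_drivers must be < n_features")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0 <= self.dependent_fraction <= 1:
            raise ValueError("dependent_fraction must lie in [0, 1]")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.noise_sd < 0 or self.class_sep < 0:
            raise ValueError("noise_sd and class_sep must be non-negative")
        if not 1 <= self.mix_sparsity <= self.n_drivers:
            raise ValueError("mix_sparsity must lie in [1, n_drivers]")
        if self.survival_driver is not None and not (
            0 <= self.survival_driver < self.n_drivers
        ):
            raise ValueError("survival_driver must index a driver")


def driver_ids(spec: SyntheticSpec) -> list[str]:
    return [f"DRIVER{i:03d}" for i in range(spec.n_drivers)]


def _feature_ids(spec: SyntheticSpec) -> tuple[list[str], list[str], list[str]]:
    n_other = spec.n_features - spec.n_drivers
    n_dep = int(round(spec.dependent_fraction * n_other))
    dep = [f"DEP{i:04d}" for i in range(n_dep)]
    noise = [f"NOISE{i:04d}" for i in range(n_other - n_dep)]
    return driver_ids(spec), dep, noise


def generate_expression(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, LabelVector, list[str]]:
    """Generate a labelled, min-max normalized cohort with known drivers.

    Returns the normalized matrix, class labels, and the planted driver IDs.
    Classes are balanced within one sample. Driver columns carry the class
    signal (consecutive class means ``class_sep`` apart, unit within-class
    noise, class-to-mean assignment permuted per driver); dependent columns
    are positive row-normalized mixes of the drivers plus N(0, noise_sd);
    remaining columns are standard Gaussian noise. Deterministic per seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    drv_ids, dep_ids, noise_ids = _feature_ids(spec)

    # balanced class assignment, shuffled
    y = np.repeat(np.arange(spec.n_classes), -(-spec.n_samples // spec.n_classes))
    y = y[: spec.n_samples]
    rng.shuffle(y)

    # drivers: class-specific means on an equally spaced grid, permuted per driver
    means = np.empty((spec.n_classes, spec.n_drivers))
    grid = spec.class_sep * np.arange(spec.n_classes)
    for j in range(spec.n_drivers):
        means[:, j] = grid[rng.permutation(spec.n_classes)]
    drivers = means[y] + rng.normal(0.0, 1.0, size=(spec.n_samples, spec.n_drivers))

    # dependent features: sparse positive mixes of drivers, rows sum to 1
    n_dep = len(dep_ids)
    if n_dep:
        mix = np.zeros((n_dep, spec.n_drivers))
        for i in range(n_dep):
            chosen = rng.choice(spec.n_drivers, size=spec.mix_sparsity, replace=False)
            w = rng.random(spec.mix_sparsity) + 0.05
            mix[i, chosen] = w / w.sum()
        dependent = drivers @ mix.T
        if spec.noise_sd > 0:
            dependent = dependent + rng.normal(
                0.0, spec.noise_sd, size=dependent.shape
            )
    else:
        dependent = np.empty((spec.n_samples, 0))

    pure = rng.normal(0.0, 1.0, size=(spec.n_samples, len(noise_ids)))

    values = np.hstack([drivers, dependent, pure])
    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    m = ExpressionMatrix(
        sample_ids=sample_ids,
        feature_ids=drv_ids + dep_ids + noise_ids,
        values=values,
    )
    m = min_max_normalize(m)
    labels = LabelVector(sample_ids=sample_ids, labels=[f"C{c}" for c in y])
    return m, labels, drv_ids


def _uniform_censor_bound(rates: np.ndarray, target: float) -> float:
    """Upper bound c of U(0, c) censoring giving the target censoring fraction.

    For an exponential event time with rate r and C ~ U(0, c),
    P(censored) = (1 - exp(-r c)) / (r c); the cohort average is solved for c.
    """

    def frac(c: float) -> float:
        rc = rates * c
        return float(np.mean((1.0 - np.exp(-rc)) / rc)) - target

    lo, hi = 1e-9, 1e-9
    while frac(hi := hi * 10) > 0:  # frac decreases from ~1-target to -target
        if hi > 1e12:
            break
    return brentq(frac, lo, hi)


def generate_survival(
    spec: SyntheticSpec,
    expression: ExpressionMatrix,
    driver_values: np.ndarray | None = None,
) -> ClinicalTable:
    """Exponential survival times with a planted median-split hazard effect.

    The hazard is ``baseline_hazard * exp(hazard_log_ratio)`` for samples whose
    survival-driver expression exceeds the cohort median and
    ``baseline_hazard`` otherwise; with ``hazard_log_ratio = 0`` the feature is
    prognostically null. Censoring times are independent U(0, c) with c chosen
    so the expected censored fraction is ``censor_rate``. Deterministic per
    seed (a seed distinct from the expression stream is derived internally).
    """
    spec.validate()
    if spec.survival_driver is None:
        raise ValueError("spec.survival_driver is not set")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 7919)))
    if driver_values is None:
        driver_values = expression.values[
            :, expression.feature_index([driver_ids(spec)[spec.survival_driver]])[0]
        ]
    driver_values = np.asarray(driver_values, dtype=float)
    high = driver_values > np.median(driver_values)
    rates = spec.baseline_hazard * np.exp(spec.hazard_log_ratio * high)

    t_event = rng.exponential(1.0 / rates)
    if spec.censor_rate > 0:
        c = _uniform_censor_bound(rates, spec.censor_rate)
        t_cens = rng.uniform(0.0, c, size=len(t_event))
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(len(t_event), dtype=int)
        time = t_event
    time = np.maximum(time, 1e-9)
    return ClinicalTable(
        sample_ids=list(expression.sample_ids), time=time, event=event
    )
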