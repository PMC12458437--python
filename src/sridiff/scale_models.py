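"""Scale models: samplers for per-sample log2 total microbial load.

Any normalization of sequence counts implicitly asserts something about the
total microbial load of each sample. This module makes that assertion
explicit and pluggable. Each model produces an ``(S, N)`` array of log2
loads — one row per Monte-Carlo replicate — to be combined with composition
replicates by the engine:

``tss_scale`` / :class:`TSSScale`
    Loads are equal across samples up to a single between-condition shift
    ``theta_perp`` drawn once per replicate from ``Normal(0, gamma^2)``.
    ``gamma = 0`` is classic total-sum scaling (no load difference assumed);
    ``gamma = 1`` (log2 units) is the default Bayesian partially-identified
    prior, asserting with 95% probability that one condition's load lies
    within a factor of roughly 0.26-3.89 of the other's.

``external_scale`` / :class:`ExternalScale`
    Loads are measured (flow cytometry, qPCR, ddPCR, ...); each replicate
    draws ``Normal(measured_log2[n], gamma^2)`` per sample, so ``gamma``
    encodes measurement error. ``gamma = 0`` uses the measurements exactly.

``predicted_scale`` / :class:`PredictedScale`
    Loads come from a predictive model and are treated as error-free: every
    replicate carries the identical prediction vector. This mirrors the
    rescale-by-predicted-load construction, which propagates no prediction
    uncertainty — a deliberate, diagnosable modelling choice.

``gamma`` is everywhere a standard deviation in log2 units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from ._utils import as_1d_float, check_finite

__all__ = [
    "ScaleSample",
    "ScaleModel",
    "TSSScale",
    "PIMScale",
    "ExternalScale",
    "PredictedScale",
    "tss_scale",
    "external_scale",
    "predicted_scale",
]

DEFAULT_PIM_GAMMA = 1.0


@dataclass
class ScaleSample:
    """Monte-Carlo draws of log2 total load, shape ``(S, N)``."""

    log2_scale: np.ndarray
    model_name: str
    gamma: float
    condition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.log2_scale = np.asarray(self.log2_scale, dtype=float)
        if self.log2_scale.ndim != 2:
            raise ValueError("log2_scale must have shape (n_replicates, n_samples)")
        check_finite(self.log2_scale, "log2_scale")

    @property
    def n_replicates(self) -> int:
        return self.log2_scale.shape[0]

    @property
    def n_samples(self) -> int:
        return self.log2_scale.shape[1]


@runtime_checkable
class ScaleModel(Protocol):
    """A configured sampler the engine can call for scale replicates."""

    name: str

    def sample(self, condition: np.ndarray, n_replicates: int, seed: int) -> ScaleSample:
        ...  # pragma: no cover - protocol


def tss_scale(
    condition: np.ndarray,
    n_replicates: int,
    gamma: float = 0.0,
    seed: int = 0,
) -> ScaleSample:
    """Sample the TSS-family scale model.

    Per replicate ``s``, a single shift ``theta_perp(s) ~ Normal(0, gamma^2)``
    is drawn and assigned to every condition-1 sample; condition-0 samples
    get log2 load 0 exactly. ``gamma = 0`` yields identically-zero scales
    (classic TSS); positive ``gamma`` relaxes the equal-load assumption.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    condition = np.asarray(condition)
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    rng = np.random.default_rng(seed)
    theta_perp = rng.normal(0.0, gamma, size=n_replicates) if gamma > 0 else np.zeros(n_replicates)
    log2_scale = theta_perp[:, None] * (condition == 1)[None, :].astype(float)
    name = "tss" if gamma == 0 else "pim"
    return ScaleSample(log2_scale=log2_scale, model_name=name, gamma=gamma, condition=condition)


def external_scale(
    measured_log2: np.ndarray,
    n_replicates: int,
    gamma: float = 0.5,
    seed: int = 0,
) -> ScaleSample:
    """Sample loads around external measurements.

    Each replicate draws ``Normal(measured_log2[n], gamma^2)`` independently
    per sample; ``gamma = 0`` returns the measurements exactly in every
    replicate.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    measured = as_1d_float(measured_log2, "measured_log2")
    if np.any(np.isnan(measured)):
        missing = np.flatnonzero(np.isnan(measured)).tolist()
        raise ValueError(f"missing load measurement for sample indices {missing}")
    check_finite(measured, "measured_log2")
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    rng = np.random.default_rng(seed)
    if gamma > 0:
        log2_scale = rng.normal(measured[None, :], gamma, size=(n_replicates, measured.size))
    else:
        log2_scale = np.tile(measured, (n_replicates, 1))
    return ScaleSample(log2_scale=log2_scale, model_name="external", gamma=gamma)


def predicted_scale(predicted_log2: np.ndarray, n_replicates: int) -> ScaleSample:
    """Use model-predicted loads verbatim, with zero scale uncertainty.

    Every replicate carries the identical prediction vector, so the
    replicate-to-replicate variance of the scale is exactly zero.
    """
    predicted = as_1d_float(predicted_log2, "predicted_log2")
    if np.any(np.isnan(predicted)):
        missing = np.flatnonzero(np.isnan(predicted)).tolist()
        raise ValueError(f"missing load prediction for sample indices {missing}")
    check_finite(predicted, "predicted_log2")
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    log2_scale = np.tile(predicted, (n_replicates, 1))
    return ScaleSample(log2_scale=log2_scale, model_name="predicted", gamma=0.0)


@dataclass(frozen=True)
class TSSScale:
    """Configured TSS-family model; ``gamma=0`` is classic TSS."""

    gamma: float = 0.0

    @property
    def name(self) -> str:
        return "tss" if self.gamma == 0 else "pim"

    def sample(self, condition, n_replicates, seed):
        return tss_scale(condition, n_replicates, gamma=self.gamma, seed=seed)


def PIMScale(gamma: float = DEFAULT_PIM_GAMMA) -> TSSScale:
    """The Bayesian partially-identified prior: TSS with load uncertainty."""
    return TSSScale(gamma=gamma)


@dataclass(frozen=True)
class ExternalScale:
    """Configured external-measurement model."""

    measured_log2: tuple[float, ...]
    gamma: float = 0.5

    def __init__(self, measured_log2, gamma: float = 0.5):
        object.__setattr__(self, "measured_log2", tuple(np.asarray(measured_log2, dtype=float)))
        object.__setattr__(self, "gamma", float(gamma))

    @property
    def name(self) -> str:
        return "external"

    def sample(self, condition, n_replicates, seed):
        return external_scale(
            np.asarray(self.measured_log2), n_replicates, gamma=self.gamma, seed=seed
        )


@dataclass(frozen=True)
class PredictedScale:
    """Configured fixed-prediction model (no scale uncertainty)."""

    predicted_log2: tuple[float, ...]

    def __init__(self, predicted_log2):
        object.__setattr__(self, "predicted_log2", tuple(np.asarray(predicted_log2, dtype=float)))

    @property
    def name(self) -> str:
        return "predicted"

    def sample(self, condition, n_replicates, seed):
        return predicted_scale(np.asarray(self.predicted_log2), n_replicates)
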