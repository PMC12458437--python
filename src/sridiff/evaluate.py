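"""Evaluation of per-sample microbial-load predictions and shift diagnostics.

Correlation alone overstates the usefulness of a load predictor: r can be
near 1 while the predictions span a tiny range, because r is invariant to
the slope of the relationship. The mean-centered coefficient of
determination used here is not — it penalizes compressed and biased
predictions while remaining invariant to the constant offsets that separate
measurement modalities (flow cytometry vs qPCR vs ddPCR). The module also
provides the covariate-shift diagnostics: how much of a model's expected
feature panel a dataset actually contains (missing features are zero-filled,
extra ones dropped — silently, as the audited pipelines do), and how often a
predictor collapses to emitting one value (mode frequency).

All load metrics operate on the log10 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_1d_float

__all__ = [
    "PairedLoads",
    "AlignmentReport",
    "sample_correlation",
    "mean_centered_r2",
    "centered_abs_residuals",
    "align_features",
    "mode_frequency",
]

logger = logging.getLogger(__name__)

MODE_FREQUENCY_DECIMALS = 6


@dataclass
class PairedLoads:
    """Measured and predicted log10 loads for the same samples.

    Inputs on a linear scale can be converted with ``from_linear``; values
    must then be strictly positive.
    """

    measured_log10: np.ndarray
    predicted_log10: np.ndarray
    sample_ids: list[str] | None = None
    modality: str = ""

    def __post_init__(self) -> None:
        self.measured_log10 = as_1d_float(self.measured_log10, "measured_log10")
        self.predicted_log10 = as_1d_float(self.predicted_log10, "predicted_log10")
        if self.measured_log10.size != self.predicted_log10.size:
            raise ValueError(
                f"length mismatch: {self.measured_log10.size} measured vs "
                f"{self.predicted_log10.size} predicted"
            )
        if self.measured_log10.size < 2:
            raise ValueError("need at least 2 paired samples")
        for name, arr in (
            ("measured_log10", self.measured_log10),
            ("predicted_log10", self.predicted_log10),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @classmethod
    def from_linear(cls, measured, predicted, **kwargs) -> "PairedLoads":
        measured = as_1d_float(measured, "measured")
        predicted = as_1d_float(predicted, "predicted")
        for name, arr in (("measured", measured), ("predicted", predicted)):
            if np.any(arr <= 0):
                raise ValueError(f"{name} has non-positive values; log10 undefined")
        return cls(np.log10(measured), np.log10(predicted), **kwargs)

    @property
    def n(self) -> int:
        return self.measured_log10.size


def _center(arr: np.ndarray) -> np.ndarray:
    # a constant vector centers to exact zeros (the mean of identical floats
    # is not always bit-exact, and the constant-predictor identity R2 = 0
    # should hold exactly)
    if np.ptp(arr) == 0:
        return np.zeros_like(arr)
    return arr - arr.mean()


def _centered(pair: PairedLoads) -> tuple[np.ndarray, np.ndarray]:
    return _center(pair.measured_log10), _center(pair.predicted_log10)


def sample_correlation(pair: PairedLoads) -> float:
    """Pearson correlation r between measured and predicted log10 loads.

    Returns NaN (with a logged warning) when either vector has zero
    variance, where r is undefined.
    """
    y, yhat = _centered(pair)
    sy = np.sqrt((y**2).sum())
    syhat = np.sqrt((yhat**2).sum())
    if sy == 0 or syhat == 0:
        logger.warning("sample_correlation undefined: zero variance in input")
        return float("nan")
    return float((y * yhat).sum() / (sy * syhat))


def mean_centered_r2(pair: PairedLoads) -> float:
    """Mean-centered coefficient of determination.

    Both vectors are centered by their own means, then
    ``R2 = 1 - SSE / SST`` with ``SSE = sum((y' - yhat')^2)`` and
    ``SST = sum(y'^2)``. Centering makes the metric invariant to constant
    offsets between measurement modalities. R2 = 1 iff the centered
    prediction equals the centered truth; 0 for any constant predictor;
    negative when worse than predicting the mean. NaN (with a warning) when
    the measurements have zero variance.
    """
    y, yhat = _centered(pair)
    sst = (y**2).sum()
    if sst == 0:
        logger.warning("mean_centered_r2 undefined: measured loads have zero variance")
        return float("nan")
    sse = ((y - yhat) ** 2).sum()
    return float(1.0 - sse / sst)


def centered_abs_residuals(pair: PairedLoads) -> np.ndarray:
    """Per-sample absolute residuals after mean-centering both vectors."""
    y, yhat = _centered(pair)
    return np.abs(y - yhat)


@dataclass
class AlignmentReport:
    """Accounting of how a dataset's features map onto a model's panel."""

    n_expected: int
    n_shared: int
    zero_filled: list[str]
    dropped_features: list[str]

    @property
    def shared_fraction(self) -> float:
        return self.n_shared / self.n_expected


def align_features(
    profile: pd.DataFrame,
    expected: list[str],
    renormalize: bool = False,
) -> tuple[pd.DataFrame, AlignmentReport]:
    """Project a taxa-by-sample profile onto a model's expected feature panel.

    The output contains exactly the expected features, in the expected
    order: features absent from the data become all-zero rows, features
    present in the data but not expected are dropped. By default no
    renormalization is performed afterwards — column sums may fall below 1,
    mirroring the silent behavior of the audited prediction pipelines.
    ``renormalize=True`` rescales each nonzero column to sum to 1.
    """
    expected = list(expected)
    if len(expected) == 0:
        raise ValueError("expected feature list must be non-empty")
    if len(set(expected)) != len(expected):
        raise ValueError("duplicate identifiers in expected feature list")
    if profile.index.has_duplicates:
        raise ValueError("duplicate identifiers in profile index")

    present = set(profile.index)
    expected_set = set(expected)
    zero_filled = [f for f in expected if f not in present]
    dropped = [f for f in profile.index if f not in expected_set]

    aligned = profile.reindex(expected, fill_value=0.0)
    if renormalize:
        sums = aligned.sum(axis=0)
        nonzero = sums > 0
        aligned.loc[:, nonzero] = aligned.loc[:, nonzero] / sums[nonzero]

    report = AlignmentReport(
        n_expected=len(expected),
        n_shared=len(expected) - len(zero_filled),
        zero_filled=zero_filled,
        dropped_features=dropped,
    )
    return aligned, report


def mode_frequency(predictions, decimals: int = MODE_FREQUENCY_DECIMALS) -> float:
    """Fraction of samples receiving the single most common predicted value.

    Values are rounded to ``decimals`` places before counting, so floats that
    agree to that precision count as equal. 1.0 means the predictor emitted
    one value for every sample (full collapse); 1/n means no repeats.
    """
    arr = as_1d_float(predictions, "predictions")
    if arr.size == 0:
        raise ValueError("predictions must be non-empty")
    _, counts = np.unique(np.round(arr, decimals), return_counts=True)
    return float(counts.max() / arr.size)
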