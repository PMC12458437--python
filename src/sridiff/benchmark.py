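"""Load-anchored ground truth and confusion scoring for any DA caller.

When external microbial-load measurements exist for every sample, they pin
down the scale that sequencing alone cannot: running the engine with the
external-measurement scale model (measurement-error sd 0.5 log2 units)
yields a reference set of calls against which any method — a different
scale model, or an external tool's exported results — can be scored with
confusion counts, PPV, NPV and FDR. Direction matters: a taxon both the
method and the truth call significant but with opposite fold-change signs
counts as a false positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import spawn_seeds
from .engine import DEFAULT_ALPHA, DAResult, run_da
from .measurement import DEFAULT_N_REPLICATES
from .scale_models import ExternalScale, PredictedScale, ScaleModel, TSSScale
from .simulate import CountTable, SyntheticDataset

__all__ = [
    "ConfusionCounts",
    "BenchmarkReport",
    "ground_truth",
    "score_against_truth",
    "run_benchmark",
    "method_tss",
    "method_pim",
    "method_external",
    "method_predicted",
]

logger = logging.getLogger(__name__)

GROUND_TRUTH_GAMMA = 0.5  # measurement-error sd (log2) of the reference scale model


@dataclass
class ConfusionCounts:
    """Confusion counts of a caller against a reference, plus derived rates.

    ``ppv``, ``npv`` and ``fdr`` are NaN when their denominator is zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else float("nan")

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "ppv": self.ppv,
            "npv": self.npv,
            "fdr": self.fdr,
        }


def ground_truth(
    counts: CountTable,
    measured_log2: np.ndarray,
    n_replicates: int = DEFAULT_N_REPLICATES,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> DAResult:
    """Reference calls from external load measurements.

    Runs the engine with the external-measurement scale model, treating each
    log2 measurement as the mean of a normal with sd 0.5 to account for
    measurement uncertainty. Deterministic given the seed.
    """
    result = run_da(
        counts,
        ExternalScale(measured_log2, gamma=GROUND_TRUTH_GAMMA),
        n_replicates=n_replicates,
        alpha=alpha,
        seed=seed,
    )
    result.meta["reference"] = True
    return result


def score_against_truth(method: DAResult, truth: DAResult) -> ConfusionCounts:
    """Confusion counts of a method's calls against reference calls.

    Per taxon: TP — both significant with the same direction; FP — method
    significant while the truth is not, or both significant with differing
    directions; FN — truth significant, method not; TN — neither
    significant. The four counts partition the taxon set.
    """
    m_taxa, t_taxa = set(method.taxa), set(truth.taxa)
    if m_taxa != t_taxa:
        only_m = sorted(m_taxa - t_taxa)
        only_t = sorted(t_taxa - m_taxa)
        raise ValueError(
            f"taxon sets differ; only in method: {only_m}, only in truth: {only_t}"
        )
    m = method.table.loc[truth.table.index]
    t = truth.table

    m_sig = m["significant"].to_numpy()
    t_sig = t["significant"].to_numpy()
    same_dir = (m["direction"].to_numpy() == t["direction"].to_numpy()) & (
        m["direction"].to_numpy() != "0"
    )

    tp = int(np.sum(m_sig & t_sig & same_dir))
    fp = int(np.sum(m_sig & ~(t_sig & same_dir)))
    fn = int(np.sum(~m_sig & t_sig))
    tn = int(np.sum(~m_sig & ~t_sig))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# method factories: resolve a scale model against a concrete dataset
# ---------------------------------------------------------------------------

MethodFactory = Callable[[SyntheticDataset], ScaleModel]


def method_tss(gamma: float = 0.0) -> MethodFactory:
    """TSS-family method (``gamma=0`` classic TSS)."""
    return lambda dataset: TSSScale(gamma=gamma)


def method_pim(gamma: float = 1.0) -> MethodFactory:
    """Bayesian partially-identified prior method."""
    return lambda dataset: TSSScale(gamma=gamma)


def method_external(gamma: float = GROUND_TRUTH_GAMMA, source: str = "measured") -> MethodFactory:
    """External-measurement method; ``source`` is ``measured`` or ``true``."""
    if source not in ("measured", "true"):
        raise ValueError("source must be 'measured' or 'true'")

    def factory(dataset: SyntheticDataset) -> ScaleModel:
        loads = (
            dataset.measured_loads_log2 if source == "measured" else dataset.true_loads_log2
        )
        return ExternalScale(loads.to_numpy(), gamma=gamma)

    return factory


def method_predicted(source: str = "true") -> MethodFactory:
    """Fixed-prediction method fed the dataset's true or measured loads."""
    if source not in ("measured", "true"):
        raise ValueError("source must be 'measured' or 'true'")

    def factory(dataset: SyntheticDataset) -> ScaleModel:
        loads = (
            dataset.measured_loads_log2 if source == "measured" else dataset.true_loads_log2
        )
        return PredictedScale(loads.to_numpy())

    return factory


@dataclass
class BenchmarkReport:
    """Per-dataset and summarized benchmark scores.

    ``per_dataset`` has one row per (dataset, method) with confusion counts
    and rates; ``medians`` one row per method with across-dataset medians of
    each rate, computed over defined (non-NaN) values only, alongside the
    count of undefined values per rate.
    """

    per_dataset: pd.DataFrame
    medians: pd.DataFrame
    failures: list[tuple[str, str]]


def run_benchmark(
    datasets: Mapping[str, SyntheticDataset] | Sequence[SyntheticDataset],
    methods: Mapping[str, MethodFactory],
    n_replicates: int = DEFAULT_N_REPLICATES,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    share_truth_seed: bool = False,
) -> BenchmarkReport:
    """Score each method against load-anchored ground truth on each dataset.

    For every dataset the reference is built once from its measured loads,
    then each method's engine run is scored against it. The ground-truth
    Monte-Carlo seed is independent of the method seeds unless
    ``share_truth_seed=True`` (useful for oracle self-tests). A dataset
    whose runs fail is recorded in ``failures`` and skipped.
    """
    if not isinstance(datasets, Mapping):
        datasets = {f"dataset_{i:03d}": d for i, d in enumerate(datasets)}
    if len(datasets) == 0 or len(methods) == 0:
        raise ValueError("need at least one dataset and one method")

    seeds = spawn_seeds(seed, len(datasets))
    rows = []
    failures: list[tuple[str, str]] = []
    for (ds_name, dataset), ds_seed in zip(datasets.items(), seeds):
        truth_seed, method_seed = spawn_seeds(ds_seed, 2)
        if share_truth_seed:
            method_seed = truth_seed
        try:
            truth = ground_truth(
                dataset.counts,
                dataset.measured_loads_log2.to_numpy(),
                n_replicates=n_replicates,
                alpha=alpha,
                seed=truth_seed,
            )
            for method_name, factory in methods.items():
                result = run_da(
                    dataset.counts,
                    factory(dataset),
                    n_replicates=n_replicates,
                    alpha=alpha,
                    seed=method_seed,
                )
                scores = score_against_truth(result, truth)
                rows.append({"dataset": ds_name, "method": method_name, **scores.as_dict()})
        except Exception as exc:  # noqa: BLE001 - harness must keep going
            logger.warning("dataset %s failed and was skipped: %s", ds_name, exc)
            failures.append((ds_name, str(exc)))

    per_dataset = pd.DataFrame(rows)
    med_rows = []
    for method_name in methods:
        sub = per_dataset[per_dataset["method"] == method_name]
        row: dict[str, object] = {"method": method_name, "n_datasets": len(sub)}
        for metric in ("fdr", "ppv", "npv"):
            vals = sub[metric].to_numpy(dtype=float)
            defined = vals[~np.isnan(vals)]
            row[f"median_{metric}"] = float(np.median(defined)) if defined.size else float("nan")
            row[f"n_undefined_{metric}"] = int(np.isnan(vals).sum())
        med_rows.append(row)
    medians = pd.DataFrame(med_rows)
    return BenchmarkReport(per_dataset=per_dataset, medians=medians, failures=failures)
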