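"""Synthetic paired count/load datasets with known absolute-abundance truth.

The generator emulates the statistical structure that scale-aware
differential-abundance analysis assumes: sparse, overdispersed sequence
counts from a two-condition design; a true per-sample total microbial load;
noisy external load measurements (flow-cytometry/qPCR-like multiplicative
error, i.e. additive on the log scale); and, for covariate-shift studies,
taxon sets that only partially overlap a training panel.

Effects are injected on *absolute* abundances, so the ground truth is
unambiguous under the composition-times-scale factorization: a taxon is
truly differential iff its absolute abundance differs between conditions,
regardless of what the compositions do. A separate ``scale_shift_log2``
multiplies all condition-1 totals, so the between-condition load difference
(the scale component of every fold change) is controllable independently of
per-taxon effects. Sequencing depth is drawn independently of load: depth
carries no information about how many microbes were in the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SimulationConfig",
    "SyntheticDataset",
    "OverlapScenario",
    "generate_paired_dataset",
    "generate_overlap_scenario",
]

_LN2 = np.log(2.0)


@dataclass
class CountTable:
    """Taxa-by-sample non-negative integer counts plus a binary condition.

    Parameters
    ----------
    counts
        DataFrame with taxa as rows and samples as columns; integer cells.
    condition
        Series of 0/1 labels indexed by sample id, aligned with the columns
        of ``counts``. May be omitted for count-only workflows (e.g. feature
        alignment); the differential-abundance engine requires it.
    """

    counts: pd.DataFrame
    condition: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.empty:
            raise ValueError("count table must be a non-empty 2-D table")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon identifiers: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                bad = np.argwhere(values != np.round(values))[0]
                raise ValueError(
                    "non-integer count at taxon "
                    f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                "negative count at taxon "
                f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
            )
        if self.condition is not None:
            cond = self.condition.reindex(self.counts.columns)
            if cond.isna().any():
                missing = cond.index[cond.isna()].tolist()
                raise ValueError(f"condition missing for samples: {missing}")
            if not set(np.unique(cond.to_numpy())) <= {0, 1}:
                raise ValueError("condition labels must be 0 or 1")
            self.condition = cond.astype(np.int64)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def condition_array(self) -> np.ndarray:
        if self.condition is None:
            raise ValueError("count table carries no condition labels")
        return self.condition.to_numpy()


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the paired counts + loads generator.

    Attributes
    ----------
    n_taxa
        Number of taxa D.
    n_per_group
        Samples per condition N (total 2N).
    frac_diff
        Fraction of taxa receiving a nonzero absolute effect.
    effect_log2
        Magnitude of each per-taxon absolute log2 fold change; the sign of
        each affected taxon is an independent fair coin flip.
    scale_shift_log2
        True between-condition scale difference: condition-1 totals are
        multiplied by ``2**scale_shift_log2``.
    depth_mean
        Median sequencing depth; realized depths are log-normal around it.
    depth_dispersion
        Log-scale (natural log) sd of the depth distribution.
    baseline_sd_log
        Between-taxon spread of baseline log (natural) abundances; ~2 gives
        the several-orders-of-magnitude range typical of gut profiles.
    sample_sd_log
        Per-sample, per-taxon biological noise sd on the natural-log scale.
    load_meas_sd_log2
        Sd of the measurement error added to the true log2 load; 0.5
        matches the measurement-uncertainty level assumed when external
        loads anchor ground truth.
    seed
        Seed for the dedicated generator; fixing it makes every output
        bit-reproducible.
    """

    n_taxa: int = 100
    n_per_group: int = 25
    frac_diff: float = 0.1
    effect_log2: float = 2.0
    scale_shift_log2: float = 0.0
    depth_mean: int = 20_000
    depth_dispersion: float = 0.3
    baseline_sd_log: float = 2.0
    sample_sd_log: float = 1.0
    load_meas_sd_log2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be at least 2 (composition undefined for D < 2)")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if not 0.0 <= self.frac_diff <= 1.0:
            raise ValueError("frac_diff must lie in [0, 1]")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be a positive integer")
        for name in ("depth_dispersion", "sample_sd_log", "load_meas_sd_log2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.baseline_sd_log <= 0:
            raise ValueError("baseline_sd_log must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticDataset:
    """A generated dataset together with its ground truth.

    ``truth_flags`` is ``"up"``/``"down"`` exactly where the per-taxon true
    absolute log2 fold change is nonzero and ``"null"`` elsewhere.
    """

    counts: CountTable
    true_loads_log2: pd.Series
    measured_loads_log2: pd.Series
    true_effects_log2: pd.Series
    truth_flags: pd.Series
    config: SimulationConfig = field(repr=False)
    #: latent absolute abundances the counts were drawn from (taxa x samples);
    #: kept in memory for factorization checks, never serialized
    latent_abundance: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def taxa(self) -> list[str]:
        return self.counts.taxa

    @property
    def samples(self) -> list[str]:
        return self.counts.samples


@dataclass
class OverlapScenario:
    """A training taxon panel plus a test dataset sharing a fraction of it."""

    train_taxa: list[str]
    test_dataset: SyntheticDataset
    rho: float

    @property
    def shared_taxa(self) -> list[str]:
        train = set(self.train_taxa)
        return [t for t in self.test_dataset.taxa if t in train]


def _taxon_ids(n: int, prefix: str = "T") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n_per_group: int) -> tuple[list[str], np.ndarray]:
    ids = [f"S{i:04d}" for i in range(1, 2 * n_per_group + 1)]
    condition = np.repeat([0, 1], n_per_group)
    return ids, condition


def generate_paired_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate one paired dataset of counts, true loads and measured loads.

    Generative model (all draws from one generator seeded by ``cfg.seed``):

    1. Baseline log abundance per taxon: ``mu_d ~ Normal(0, baseline_sd_log^2)``.
    2. A uniformly chosen subset of ``floor(frac_diff * D)`` taxa receives an
       absolute effect of magnitude ``effect_log2`` log2 units, each sign an
       independent fair Bernoulli.
    3. Per-sample absolute abundance is log-normal around baseline +
       condition effect, with sd ``sample_sd_log``; condition-1 samples are
       additionally multiplied by ``2**scale_shift_log2``.
    4. True load is the per-sample total of absolute abundances; the measured
       load adds ``Normal(0, load_meas_sd_log2^2)`` on the log2 scale.
    5. Depth is log-normal around ``depth_mean`` (independent of load), and
       counts are multinomial at that depth from the sample's proportions.
    """
    rng = np.random.default_rng(cfg.seed)
    D, N = cfg.n_taxa, cfg.n_per_group
    taxa = _taxon_ids(D)
    samples, condition = _sample_ids(N)

    mu = rng.normal(0.0, cfg.baseline_sd_log, size=D)

    n_diff = int(np.floor(cfg.frac_diff * D))
    effects_log2 = np.zeros(D)
    if n_diff > 0:
        which = rng.choice(D, size=n_diff, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_diff)
        effects_log2[which] = signs * cfg.effect_log2

    noise = rng.normal(0.0, cfg.sample_sd_log, size=(D, 2 * N))
    log_abs = mu[:, None] + (effects_log2 * _LN2)[:, None] * condition[None, :] + noise
    log_abs = log_abs + (cfg.scale_shift_log2 * _LN2) * condition[None, :]
    abs_abundance = np.exp(log_abs)

    true_loads = abs_abundance.sum(axis=0)
    true_loads_log2 = np.log2(true_loads)
    measured_loads_log2 = true_loads_log2 + rng.normal(
        0.0, cfg.load_meas_sd_log2, size=2 * N
    )

    depths = np.maximum(
        1,
        np.round(
            rng.lognormal(np.log(cfg.depth_mean), cfg.depth_dispersion, size=2 * N)
        ).astype(np.int64),
    )
    proportions = abs_abundance / true_loads[None, :]
    counts = np.empty((D, 2 * N), dtype=np.int64)
    for n in range(2 * N):
        counts[:, n] = rng.multinomial(depths[n], proportions[:, n])

    flags = np.where(effects_log2 > 0, "up", np.where(effects_log2 < 0, "down", "null"))
    table = CountTable(
        counts=pd.DataFrame(counts, index=taxa, columns=samples),
        condition=pd.Series(condition, index=samples, name="condition"),
    )
    return SyntheticDataset(
        counts=table,
        true_loads_log2=pd.Series(true_loads_log2, index=samples, name="log2_true"),
        measured_loads_log2=pd.Series(
            measured_loads_log2, index=samples, name="log2_measured"
        ),
        true_effects_log2=pd.Series(effects_log2, index=taxa, name="true_effect_log2"),
        truth_flags=pd.Series(flags, index=taxa, name="truth_flag"),
        config=cfg,
        latent_abundance=pd.DataFrame(abs_abundance, index=taxa, columns=samples),
    )


def generate_overlap_scenario(cfg: SimulationConfig, rho: float) -> OverlapScenario:
    """Generate a test dataset whose taxon set overlaps a training panel.

    The training panel has ``cfg.n_taxa`` identifiers. The test dataset is a
    fresh draw from ``cfg`` whose taxa are relabelled so that exactly
    ``round(rho * n_taxa)`` of them carry training identifiers (a uniformly
    chosen subset) and the rest carry novel identifiers.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    dataset = generate_paired_dataset(cfg)
    D = cfg.n_taxa
    train_taxa = _taxon_ids(D, prefix="TRAIN")
    novel_taxa = _taxon_ids(D, prefix="NOVEL")

    n_shared = int(round(rho * D))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0E22]))
    shared = rng.choice(D, size=n_shared, replace=False)
    new_names = list(novel_taxa)
    for i, idx in enumerate(sorted(shared)):
        new_names[idx] = train_taxa[i]

    mapping = dict(zip(dataset.taxa, new_names))
    dataset.counts.counts = dataset.counts.counts.rename(index=mapping)
    dataset.true_effects_log2 = dataset.true_effects_log2.rename(index=mapping)
    dataset.truth_flags = dataset.truth_flags.rename(index=mapping)
    return OverlapScenario(train_taxa=train_taxa, test_dataset=dataset, rho=rho)


def expected_absolute_abundance(
    dataset: SyntheticDataset,
) -> pd.DataFrame:  # pragma: no cover - convenience for notebooks
    """Reconstruct absolute abundances as proportions times true load."""
    counts = dataset.counts.counts.to_numpy(dtype=float)
    props = counts / counts.sum(axis=0, keepdims=True)
    abs_est = props * np.exp2(dataset.true_loads_log2.to_numpy())[None, :]
    return pd.DataFrame(abs_est, index=dataset.taxa, columns=dataset.samples)
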