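"""Monte-Carlo differential-abundance engine on absolute abundances.

The engine joins the two replicate streams — compositions from the
measurement model and log2 loads from a scale model — into log2 absolute
abundances ``log2 W_dn(s) = log2 Wpar_dn(s) + log2 Wperp_n(s)``, estimates
per-replicate log2 fold changes between the two conditions, tests each taxon
with a Wilcoxon rank-sum test, adjusts with Benjamini-Hochberg within each
replicate, and averages across replicates so that the final p-values carry
uncertainty from both sampling noise and the scale assumption.

The central identity, preserved exactly throughout: every per-replicate
fold change decomposes as ``theta_d = theta_d_par + theta_perp``, the
compositional part plus the shared scale part.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import spawn_seeds
from .measurement import (
    DEFAULT_N_REPLICATES,
    DEFAULT_PRIOR_MASS,
    CompositionReplicates,
    draw_compositions,
)
from .scale_models import ScaleModel, ScaleSample
from .simulate import CountTable

__all__ = [
    "DAResult",
    "ThetaReplicates",
    "absolute_replicates",
    "estimate_theta",
    "wilcoxon_rank_sum",
    "benjamini_hochberg",
    "run_da",
]

EXACT_MODE_MAX_N = 16  # full enumeration above this is needlessly slow
DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# replicate algebra
# ---------------------------------------------------------------------------

def absolute_replicates(comp: CompositionReplicates, scale: ScaleSample) -> np.ndarray:
    """Combine composition and scale replicates into log2 absolute abundances.

    Returns an ``(S, D, N)`` array with
    ``out[s, d, n] = log2(comp.values[s, d, n]) + scale.log2_scale[s, n]``.
    """
    S, D, N = comp.values.shape
    if scale.log2_scale.shape != (S, N):
        raise ValueError(
            f"scale shape {scale.log2_scale.shape} does not match "
            f"composition replicates (S={S}, N={N})"
        )
    return np.log2(comp.values) + scale.log2_scale[:, None, :]


@dataclass
class ThetaReplicates:
    """Per-replicate fold-change estimates and their decomposition.

    ``theta``, ``theta_par`` have shape ``(S, D)``; ``theta_perp`` has shape
    ``(S,)`` (the scale part is shared by all taxa within a replicate).
    ``theta == theta_par + theta_perp[:, None]`` holds exactly: ``theta`` is
    defined as that sum, and the equivalence with the group-mean difference
    of log2 absolute abundances is a tested identity.
    """

    theta: np.ndarray
    theta_par: np.ndarray
    theta_perp: np.ndarray


def _group_mean_diff(values: np.ndarray, condition: np.ndarray) -> np.ndarray:
    """Mean over condition-1 samples minus mean over condition-0 samples.

    Operates on the last axis of ``values``.
    """
    condition = np.asarray(condition)
    mask1 = condition == 1
    mask0 = condition == 0
    if not mask1.any() or not mask0.any():
        raise ValueError("both conditions must contain at least one sample")
    return values[..., mask1].mean(axis=-1) - values[..., mask0].mean(axis=-1)


def estimate_theta(
    comp: CompositionReplicates, scale: ScaleSample, condition: np.ndarray
) -> ThetaReplicates:
    """Estimate per-replicate fold changes and their decomposition.

    ``theta_par(s, d)`` is the between-condition difference of group means of
    log2 compositions; ``theta_perp(s)`` the same on log2 scales; ``theta``
    their sum — identical (to floating point linearity of the mean) to the
    group-mean difference computed directly on log2 absolute abundances.
    """
    theta_par = _group_mean_diff(np.log2(comp.values), condition)
    theta_perp = _group_mean_diff(scale.log2_scale, condition)
    return ThetaReplicates(
        theta=theta_par + theta_perp[:, None],
        theta_par=theta_par,
        theta_perp=theta_perp,
    )


# ---------------------------------------------------------------------------
# hypothesis testing primitives
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(
    x: np.ndarray,
    y: np.ndarray,
    mode: Literal["exact", "normal", "auto"] = "auto",
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``exact`` enumerates the permutation null of the rank sum, using
    mid-ranks for ties, and returns ``P(|T - E T| >= |t_obs - E T|)`` — valid
    only for combined sample sizes up to 16. ``normal`` uses the
    tie-corrected normal approximation without continuity correction.
    ``auto`` picks ``exact`` when ``len(x) + len(y) <= 16``.

    Two groups with completely identical values give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = x.size, y.size
    if mode == "auto":
        mode = "exact" if n + m <= EXACT_MODE_MAX_N else "normal"

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    t_obs = ranks[:n].sum()
    expect = n * (n + m + 1) / 2.0

    if mode == "exact":
        if n + m > EXACT_MODE_MAX_N:
            raise ValueError(
                f"exact mode supports combined n <= {EXACT_MODE_MAX_N}, got {n + m}"
            )
        dev_obs = abs(t_obs - expect)
        hits = 0
        total = math.comb(n + m, n)
        for subset in combinations(range(n + m), n):
            t = ranks[list(subset)].sum()
            # tolerance guards half-integer mid-rank arithmetic
            if abs(t - expect) >= dev_obs - 1e-9:
                hits += 1
        return hits / total

    var = _rank_sum_variance(ranks, n, m)
    if var <= 0:
        return 1.0
    z = (t_obs - expect) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def _rank_sum_variance(ranks: np.ndarray, n: int, m: int) -> float:
    """Tie-corrected null variance of the rank sum of the first group."""
    N = n + m
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    return n * m / 12.0 * (N + 1 - tie_term / (N * (N - 1)))


def _rank_sum_pvalues_matrix(values: np.ndarray, condition: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected normal-approximation rank-sum p-values.

    ``values`` has shape ``(..., N)``; each row along the last axis is tested
    for a location difference between conditions. Rows whose two groups are
    completely identical get p = 1. Used by the engine, where rows are
    (replicate, taxon) slices of continuous Monte-Carlo draws — ties are
    essentially impossible there, but the tie correction is applied whenever
    ties do occur.
    """
    condition = np.asarray(condition)
    N = values.shape[-1]
    n1 = int((condition == 1).sum())
    n0 = int((condition == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both conditions must contain at least one sample")

    flat = values.reshape(-1, N)
    ranks = stats.rankdata(flat, axis=1)
    t = ranks[:, condition == 1].sum(axis=1)
    expect = n1 * (N + 1) / 2.0
    var = np.full(flat.shape[0], n1 * n0 * (N + 1) / 12.0)

    # tie correction, computed only for rows that actually contain ties
    srt = np.sort(flat, axis=1)
    has_ties = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
    if has_ties.any():
        for i in np.flatnonzero(has_ties):
            var[i] = _rank_sum_variance(ranks[i], n1, n0)

    p = np.ones(flat.shape[0])
    nonzero = var > 0
    z = (t[nonzero] - expect) / np.sqrt(var[nonzero])
    p[nonzero] = 2.0 * stats.norm.sf(np.abs(z))
    return p.reshape(values.shape[:-1])


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Accepts a 1-D vector or an array whose last axis indexes hypotheses
    (adjustment is applied independently along it). Input order is preserved;
    output is capped at 1. Implemented directly (sort, scale by m/rank, take
    the running minimum from the tail) so it vectorizes across the engine's
    Monte-Carlo replicates.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.shape[-1]
    order = np.argsort(p, axis=-1)
    ranked = np.take_along_axis(p, order, axis=-1)
    scaled = ranked * (m / np.arange(1, m + 1))
    adjusted = np.minimum.accumulate(scaled[..., ::-1], axis=-1)[..., ::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    np.put_along_axis(out, order, adjusted, axis=-1)
    return out


# ---------------------------------------------------------------------------
# the full engine
# ---------------------------------------------------------------------------

@dataclass
class DAResult:
    """Per-taxon differential-abundance calls averaged over replicates.

    ``table`` is indexed by taxon with columns ``theta`` (mean log2 fold
    change), ``theta_par`` (compositional part), ``theta_perp`` (scale part),
    ``p_adj`` (mean within-replicate BH-adjusted p), ``significant``
    (``p_adj < alpha``) and ``direction`` (``+``, ``-`` or ``0``, the sign of
    ``theta``).
    """

    table: pd.DataFrame
    alpha: float
    n_replicates: int
    scale_model: str
    seed: int
    p_average: str = "adjusted"
    meta: dict = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return list(self.table.index)

    @property
    def significant_taxa(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "taxon", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _directions(theta: np.ndarray) -> np.ndarray:
    return np.where(theta > 0, "+", np.where(theta < 0, "-", "0"))


def run_da(
    counts: CountTable,
    scale_model: ScaleModel,
    n_replicates: int = DEFAULT_N_REPLICATES,
    alpha: float = DEFAULT_ALPHA,
    prior_mass: float = DEFAULT_PRIOR_MASS,
    seed: int = 0,
    p_average: Literal["adjusted", "raw"] = "adjusted",
) -> DAResult:
    """Run the full Monte-Carlo differential-abundance analysis.

    For each of ``n_replicates`` joint draws: compositions come from the
    Dirichlet measurement model, log2 loads from ``scale_model``, their sum
    gives log2 absolute abundances, each taxon is tested across conditions
    with the rank-sum test, and BH adjustment is applied across taxa within
    the replicate. Reported per-taxon quantities are means over replicates;
    a taxon is significant when its mean adjusted p falls below ``alpha``.

    ``p_average="raw"`` instead averages the raw p-values over replicates
    and applies BH once to the averages (non-default alternative).
    """
    if counts.n_taxa < 2:
        raise ValueError("differential abundance requires at least 2 taxa")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    condition = counts.condition_array()
    if {0, 1} - set(np.unique(condition)):
        raise ValueError("both conditions must be present in the design")

    comp_seed, scale_seed = spawn_seeds(seed, 2)
    comp = draw_compositions(counts, n_replicates, prior_mass=prior_mass, seed=comp_seed)
    scale = scale_model.sample(condition, n_replicates, scale_seed)

    log2_abs = absolute_replicates(comp, scale)
    thetas = estimate_theta(comp, scale, condition)

    # (S, D) raw p-values; tests run on log2 absolute abundances
    p_raw = _rank_sum_pvalues_matrix(log2_abs, condition)

    if p_average == "adjusted":
        p_adj = benjamini_hochberg(p_raw).mean(axis=0)
    elif p_average == "raw":
        p_adj = benjamini_hochberg(p_raw.mean(axis=0))
    else:
        raise ValueError("p_average must be 'adjusted' or 'raw'")

    theta_mean = thetas.theta.mean(axis=0)
    theta_par_mean = thetas.theta_par.mean(axis=0)
    theta_perp_mean = float(thetas.theta_perp.mean())

    table = pd.DataFrame(
        {
            "theta": theta_mean,
            "theta_par": theta_par_mean,
            "theta_perp": theta_perp_mean,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
            "direction": _directions(theta_mean),
        },
        index=pd.Index(counts.taxa, name="taxon"),
    )
    return DAResult(
        table=table,
        alpha=alpha,
        n_replicates=n_replicates,
        scale_model=scale.model_name,
        seed=seed,
        p_average=p_average,
        meta={"prior_mass": prior_mass, "gamma": scale.gamma},
    )
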