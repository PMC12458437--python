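"""Measurement model: Dirichlet posterior replicates of composition.

Sequence counts inform per-sample proportions only up to multinomial
sampling noise. The measurement model here is the conjugate one: for each
sample with count vector ``y``, composition replicates are drawn from
``Dirichlet(y + prior_mass)``. Zeros in the counts therefore yield strictly
positive but stochastically small proportions — no pseudocount is ever added
to the data itself, only to the prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import CountTable

__all__ = ["CompositionReplicates", "draw_compositions"]

logger = logging.getLogger(__name__)

DEFAULT_PRIOR_MASS = 0.5
DEFAULT_N_REPLICATES = 128


@dataclass
class CompositionReplicates:
    """Monte-Carlo draws of per-sample composition.

    ``values`` has shape ``(n_replicates, n_taxa, n_samples)``; each
    ``values[s, :, n]`` lies on the simplex.
    """

    values: np.ndarray
    taxa: list[str]
    samples: list[str]
    prior_mass: float
    n_replicates: int
    seed: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def draw_compositions(
    counts: CountTable,
    n_replicates: int = DEFAULT_N_REPLICATES,
    prior_mass: float = DEFAULT_PRIOR_MASS,
    seed: int = 0,
) -> CompositionReplicates:
    """Draw ``n_replicates`` Dirichlet posterior compositions per sample.

    For sample ``n`` with counts ``y[:, n]`` each replicate is an independent
    draw from ``Dirichlet(y[:, n] + prior_mass)``. Samples are independent of
    each other. Deterministic for a fixed ``seed``.

    Raises
    ------
    ValueError
        If ``n_replicates < 1``, ``prior_mass < 0``, or a sample has zero
        total count while ``prior_mass == 0`` (the posterior is undefined).
        A zero-total sample with positive prior mass is allowed: its draws
        come from the uniform-mass prior alone, and a warning is logged.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if prior_mass < 0:
        raise ValueError("prior_mass must be non-negative")

    y = counts.counts.to_numpy(dtype=float)
    totals = y.sum(axis=0)
    if np.any(totals == 0):
        empty = [s for s, t in zip(counts.samples, totals) if t == 0]
        if prior_mass == 0:
            raise ValueError(
                f"samples with zero total count and prior_mass=0: {empty} "
                "(posterior undefined)"
            )
        logger.warning(
            "samples %s have zero total count; compositions drawn from the "
            "uniform Dirichlet(prior_mass=%g) prior alone",
            empty,
            prior_mass,
        )

    alpha = y + prior_mass
    rng = np.random.default_rng(seed)
    # Gamma-normalization construction of the Dirichlet, vectorized over
    # replicates and samples in one call.
    gammas = rng.standard_gamma(alpha, size=(n_replicates, *alpha.shape))
    values = gammas / gammas.sum(axis=1, keepdims=True)
    return CompositionReplicates(
        values=values,
        taxa=counts.taxa,
        samples=counts.samples,
        prior_mass=prior_mass,
        n_replicates=n_replicates,
        seed=seed,
    )
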