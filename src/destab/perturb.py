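"""Mixture perturbation of count matrices.

Each cell (g, i) of the observed matrix keeps its value with probability
alpha0 = 1 - alpha1 and is otherwise replaced by a fresh draw from the
fitted NB(mu_gi, phi_g). A grid of perturbation sizes alpha1 in
(0, alpha_max] with M replicates per size drives the stability curve.

RNG discipline: one master seed spawns a deterministic substream per
(grid index, replicate), so refining the grid never changes the counts of
existing replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .countdata import CountMatrix
from .nbmodel import NBParams, sample_nb

__all__ = ["PerturbationConfig", "perturbation_grid", "perturb", "replicate_rng"]


@dataclass
class PerturbationConfig:
    """Grid of perturbation sizes and replicate count.

    alpha_max : largest perturbation size alpha1 (default 0.1).
    n_grid    : number of evenly spaced grid points in (0, alpha_max].
    M         : perturbed replicates per grid point.
    seed      : master seed for all perturbation randomness.
    """

    alpha_max: float = 0.1
    n_grid: int = 10
    M: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha_max <= 1):
            raise ValueError("alpha_max must be in (0, 1]")
        if self.n_grid < 1:
            raise ValueError("n_grid must be >= 1")
        if self.M < 1:
            raise ValueError("M must be >= 1")


def perturbation_grid(config: PerturbationConfig) -> np.ndarray:
    """Evenly spaced alpha1 values alpha_max * (1..n_grid) / n_grid.

    Excludes 0 (the unperturbed anchor is handled by the stability curve)
    and includes alpha_max.
    """
    k = np.arange(1, config.n_grid + 1)
    return config.alpha_max * k / config.n_grid


def replicate_rng(config: PerturbationConfig, grid_index: int, m: int) -> np.random.Generator:
    """Independent, reproducible substream for (grid point, replicate).

    ``grid_index = -1`` is reserved for the unperturbed original run; the
    internal +1 offset keeps all spawn keys non-negative.
    """
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(grid_index + 1, m))
    return np.random.default_rng(ss)


def perturb(
    cm: CountMatrix, params: NBParams, alpha1: float, rng: np.random.Generator
) -> CountMatrix:
    """One perturbed matrix from the mixture with perturbation size alpha1.

    Per cell: Bernoulli(1 - alpha1) keeps the observed count, otherwise the
    cell is resampled from NB(mu_gi, phi_g). alpha1 = 0 returns the input
    counts unchanged; alpha1 = 1 resamples every cell.
    """
    if params.mu.shape != cm.shape:
        raise ValueError(
            f"NBParams shape {params.mu.shape} does not match counts {cm.shape}"
        )
    if not (0 <= alpha1 <= 1):
        raise ValueError("alpha1 must be in [0, 1]")
    if alpha1 == 0:
        return CountMatrix(cm.counts.copy(), cm.feature_ids, cm.sample_ids)
    resample = rng.random(cm.shape) < alpha1
    new = cm.counts.copy()
    if resample.any():
        g_idx, i_idx = np.nonzero(resample)
        new[g_idx, i_idx] = sample_nb(
            params.mu[g_idx, i_idx], params.phi[g_idx], rng
        )
    return CountMatrix(new, cm.feature_ids, cm.sample_ids)
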