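"""Synthetic two-group RNA-seq count data with known truth.

Datasets are drawn feature-by-feature from NB(mu, phi) with a realistic
decreasing mean-dispersion trend. The default configuration is the basic
study design used throughout the evaluation harness: 10,000 features, 3
replicates per condition, 10% DE features of which 50% are up-regulated,
fold changes ~ N(3, 0.5^2) truncated below at 1, equal library sizes.
Outliers can be injected by three mechanisms (factors ~ U(1.5, 10)):

    S - per selected feature, exactly one sample's count is multiplied;
    R - each cell independently multiplied with some probability;
    M - each cell independently resampled from NB with an inflated mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np

from .countdata import CountMatrix, GroupDesign
from .nbmodel import sample_nb

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "sample_mean_dispersion_pairs",
    "draw_truth",
    "draw_counts",
    "simulate_dataset",
    "inject_outliers",
]


@dataclass
class SimulationConfig:
    """Generator settings; the defaults are the basic study design."""

    n_features: int = 10_000
    n_per_group: int = 3
    p_de: float = 0.10
    p_up: float = 0.5
    fc_mean: float = 3.0
    fc_sd: float = 0.5
    disp_ratio: float = 1.0
    p_outlier: float = 0.0
    outlier_mech: str = "none"  # none | S | R | M
    outlier_factor_range: tuple[float, float] = (1.5, 10.0)
    seed: int = 0
    pair_source: str = "parametric"  # parametric | fixture

    def __post_init__(self) -> None:
        if not (0 <= self.p_de < 1 and 0 <= self.p_up <= 1 and 0 <= self.p_outlier <= 1):
            raise ValueError("probabilities must be in range")
        if self.outlier_mech not in ("none", "S", "R", "M"):
            raise ValueError("outlier_mech must be one of none/S/R/M")
        if self.fc_mean <= 0 or self.fc_sd <= 0 or self.disp_ratio <= 0:
            raise ValueError("fc_mean, fc_sd and disp_ratio must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outlier_factor_range"] = list(self.outlier_factor_range)
        return d


@dataclass
class TruthLabels:
    """Ground truth: DE flags, direction, fold changes, NB parameters.

    ``true_mu`` has shape (G, 2): per-condition means (column 0 = condition
    A, column 1 = condition B). ``true_fc`` is exactly 1 for non-DE
    features.
    """

    is_de: np.ndarray
    is_up: np.ndarray
    true_fc: np.ndarray
    true_mu: np.ndarray
    true_phi: np.ndarray

    @property
    def true_lfc(self) -> np.ndarray:
        """Signed log2 fold change (B vs A)."""
        return np.log2(self.true_mu[:, 1]) - np.log2(self.true_mu[:, 0])


def sample_mean_dispersion_pairs(
    G: int, source: str = "parametric", rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw G (mean, dispersion) pairs with a decreasing dispersion trend.

    ``parametric``: log-means ~ Normal(log 50, 1.5^2), truncated to
    [0.5, 1e5]; dispersions (0.1 + 2/mu) jittered by lognormal noise with
    sd of log 0.4 — a bulk-RNA-seq-like profile where low-abundance
    features are noisier. ``fixture`` resamples with replacement from a
    packaged table of ~1000 pairs generated once from the same parametric
    model (a synthetic stand-in for parameter pairs fitted to a large real
    dataset; see the table's filename).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if source == "parametric":
        mu = np.exp(rng.normal(np.log(50.0), 1.5, size=G))
        mu = np.clip(mu, 0.5, 1e5)
        phi = (0.1 + 2.0 / mu) * np.exp(rng.normal(0.0, 0.4, size=G))
        return mu, phi
    if source == "fixture":
        table = _load_pair_fixture()
        idx = rng.integers(0, len(table), size=G)
        return table[idx, 0].copy(), table[idx, 1].copy()
    raise ValueError("pair source must be 'parametric' or 'fixture'")


def _load_pair_fixture() -> np.ndarray:
    with resources.files("destab.data").joinpath(
        "synthetic_mean_dispersion_pairs.tsv"
    ).open("r") as fh:
        return np.loadtxt(fh, delimiter="\t", skiprows=1)


def draw_truth(config: SimulationConfig, rng: np.random.Generator) -> TruthLabels:
    """Draw the population parameters: (mu, phi) pairs, DE flags, fold changes."""
    G = config.n_features
    mu0, phi = sample_mean_dispersion_pairs(G, config.pair_source, rng)
    phi = phi * config.disp_ratio
    n_de = int(round(config.p_de * G))
    n_up = int(round(config.p_up * n_de))
    de_idx = rng.choice(G, size=n_de, replace=False)
    is_de = np.zeros(G, dtype=bool)
    is_de[de_idx] = True
    is_up = np.zeros(G, dtype=bool)
    is_up[de_idx[:n_up]] = True
    fc = np.ones(G)
    fc[is_de] = np.maximum(rng.normal(config.fc_mean, config.fc_sd, size=n_de), 1.0)
    mu_a = mu0.copy()
    mu_b = mu0.copy()
    up = is_de & is_up
    down = is_de & ~is_up
    mu_b[up] = mu0[up] * fc[up]
    mu_b[down] = mu0[down] / fc[down]
    return TruthLabels(
        is_de=is_de,
        is_up=is_up,
        true_fc=fc,
        true_mu=np.column_stack([mu_a, mu_b]),
        true_phi=phi,
    )


def draw_counts(
    truth: TruthLabels, n_per_group: int, rng: np.random.Generator
) -> tuple[CountMatrix, GroupDesign]:
    """One dataset of NB counts from the truth parameters, equal library sizes."""
    G = len(truth.true_phi)
    mu = np.hstack(
        [
            np.repeat(truth.true_mu[:, [0]], n_per_group, axis=1),
            np.repeat(truth.true_mu[:, [1]], n_per_group, axis=1),
        ]
    )
    counts = sample_nb(mu, truth.true_phi[:, None], rng)
    fids = [f"g{i+1}" for i in range(G)]
    sids = [f"A{i+1}" for i in range(n_per_group)] + [
        f"B{i+1}" for i in range(n_per_group)
    ]
    design = GroupDesign(["A"] * n_per_group + ["B"] * n_per_group)
    return CountMatrix(counts, fids, sids), design


def simulate_dataset(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, GroupDesign, TruthLabels, np.ndarray]:
    """Full generator: truth draw, NB counts, optional outlier injection.

    Returns (counts, design, truth, outlier_mask); the mask is all-False
    when no outliers are configured.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = draw_truth(config, rng)
    cm, design = draw_counts(truth, config.n_per_group, rng)
    if config.outlier_mech != "none" and config.p_outlier > 0:
        cm, mask = inject_outliers(
            cm,
            config.outlier_mech,
            config.p_outlier,
            config.outlier_factor_range,
            truth,
            rng,
            n_per_group=config.n_per_group,
        )
    else:
        mask = np.zeros(cm.shape, dtype=bool)
    return cm, design, truth, mask


def inject_outliers(
    cm: CountMatrix,
    mech: str,
    prob: float,
    factor_range: tuple[float, float],
    truth: TruthLabels | None,
    rng: np.random.Generator,
    n_per_group: int | None = None,
) -> tuple[CountMatrix, np.ndarray]:
    """Inject outlier counts by mechanism S, R or M; factors ~ U(lo, hi).

    S: each feature selected with probability ``prob``; one uniformly
    chosen sample of each selected feature is multiplied by a factor
    (at most one outlier per feature). R: each cell independently
    multiplied with probability ``prob``. M: each cell independently, with
    probability ``prob``, resampled from NB(true mu * factor, true phi) —
    this mechanism needs the truth parameters. Multiplied counts are
    rounded to the nearest integer so they stay on the NB support.
    """
    if not (0 <= prob <= 1):
        raise ValueError("outlier probability must be in [0, 1]")
    lo, hi = factor_range
    G, n = cm.shape
    counts = cm.counts.copy()
    mask = np.zeros((G, n), dtype=bool)
    if mech == "S":
        chosen = rng.random(G) < prob
        cols = rng.integers(0, n, size=G)
        rows = np.flatnonzero(chosen)
        cols = cols[rows]
        factors = rng.uniform(lo, hi, size=len(rows))
        counts[rows, cols] = np.rint(counts[rows, cols] * factors).astype(np.int64)
        mask[rows, cols] = True
    elif mech == "R":
        mask = rng.random((G, n)) < prob
        factors = rng.uniform(lo, hi, size=int(mask.sum()))
        counts[mask] = np.rint(counts[mask] * factors).astype(np.int64)
    elif mech == "M":
        if truth is None:
            raise ValueError("mechanism M needs the truth parameters (mu, phi)")
        if n_per_group is None:
            n_per_group = n // 2
        mu = np.hstack(
            [
                np.repeat(truth.true_mu[:, [0]], n_per_group, axis=1),
                np.repeat(truth.true_mu[:, [1]], n - n_per_group, axis=1),
            ]
        )
        mask = rng.random((G, n)) < prob
        if mask.any():
            g_idx, i_idx = np.nonzero(mask)
            factors = rng.uniform(lo, hi, size=len(g_idx))
            counts[mask] = sample_nb(
                mu[g_idx, i_idx] * factors, truth.true_phi[g_idx], rng
            )
    else:
        raise ValueError("outlier mechanism must be S, R or M")
    return CountMatrix(counts, cm.feature_ids, cm.sample_ids), mask
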