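"""Selection-set similarity, the Ave(alpha1) curve and the AUCOR summary.

Two selected feature sets over the same universe of G features are compared
with the truncated phi coefficient

    rho(s1, s2) = max(0, (k - k1*k2/G) / (G * v1 * v2)),
    v_j = sqrt((k_j/G) * (1 - k_j/G)),

i.e. the Pearson correlation of the two binary indicator vectors, floored
at zero, and defined as 0 whenever either set is empty or full. For each
perturbation size alpha1 on a grid, M perturbed datasets are generated, the
DE method re-run, and Ave(alpha1) is the mean rho between each perturbed
selection and the original selection s0. AUCOR is the trapezoidal area
under the (alpha1, Ave) curve over [0, alpha_max], normalized by
1/alpha_max, so 1 means perfectly stable and 0 maximally unstable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .countdata import CountMatrix, GroupDesign, cpm, size_factors
from .de import SelectionSet, run_de, select
from .nbmodel import estimate_nb_params
from .perturb import PerturbationConfig, perturb, perturbation_grid, replicate_rng

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationCurve",
    "AucorResult",
    "phi_similarity",
    "proportion_intersection",
    "ave_curve",
    "aucor",
    "compute_aucor",
    "aucor_stratified",
]


@dataclass
class CorrelationCurve:
    """(alpha1, Ave) pairs including the left anchor at alpha1 = 0.

    ``per_replicate`` holds the M x n_grid matrix of individual rho values
    (anchor column excluded); ``ave`` is its column mean prepended with the
    anchor value (1 when s0 is non-empty, 0 in the degenerate empty-s0
    regime where every rho is 0 by convention).
    """

    alphas: np.ndarray
    ave: np.ndarray
    per_replicate: np.ndarray
    M: int

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.ave = np.asarray(self.ave, dtype=float)


@dataclass
class AucorResult:
    """AUCOR value with the curve and settings that produced it."""

    aucor: float
    curve: CorrelationCurve
    config: PerturbationConfig
    method_name: str
    threshold: float
    s0_size: int = 0


def _indicators(s1: SelectionSet, s2: SelectionSet) -> tuple[np.ndarray, np.ndarray]:
    if s1.universe_size != s2.universe_size:
        raise ValueError(
            f"selection sets live in different universes "
            f"({s1.universe_size} vs {s2.universe_size})"
        )
    return s1.indicator, s2.indicator


def phi_similarity(s1: SelectionSet, s2: SelectionSet) -> float:
    """Truncated phi coefficient between two selection sets.

    Returns max(0, Pearson correlation of the indicator vectors); 0 when
    either set is empty or full (degenerate variance), which makes a method
    that selects nothing maximally unstable by convention.
    """
    a, b = _indicators(s1, s2)
    G = len(a)
    k1, k2 = int(a.sum()), int(b.sum())
    if k1 in (0, G) or k2 in (0, G):
        return 0.0
    k = int((a & b).sum())
    # integer-exact form of (k - k1*k2/G) / (G*v1*v2): identical sets give 1.0
    num = k * G - k1 * k2
    den = np.sqrt(float(k1) * (G - k1) * k2 * (G - k2))
    return max(0.0, num / den)


def proportion_intersection(s1: SelectionSet, s2: SelectionSet) -> float:
    """|A intersect B| / ((|A| + |B|) / 2); 0 when both sets are empty."""
    a, b = _indicators(s1, s2)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def aucor(curve: CorrelationCurve) -> float:
    """Normalized trapezoidal area under the correlation curve.

    The curve must contain the alpha1 = 0 anchor and strictly increasing
    alphas; the area over [0, alpha_max] is divided by alpha_max.
    """
    a = curve.alphas
    if len(a) < 2:
        raise ValueError("curve needs at least two points including the anchor")
    if np.any(np.diff(a) <= 0):
        raise ValueError("curve alphas must be strictly increasing")
    return float(np.trapezoid(curve.ave, a) / (a[-1] - a[0]))


def _perturbation_selections(
    cm: CountMatrix,
    design: GroupDesign,
    method,
    config: PerturbationConfig,
    threshold: float = 0.05,
    norm_method: str = "median_ratio",
    robust_dispersion: bool = True,
    return_results: bool = False,
):
    """Shared pipeline: fit NB once, perturb over the grid, re-run DE.

    Returns (s0, grid, selections) where selections[j][m] is the
    SelectionSet (or, with ``return_results``, the DEResult) for grid point
    j, replicate m.
    """
    from .de import get_method

    if isinstance(method, str):
        method = get_method(method)
    norm = size_factors(cm, norm_method)
    params = estimate_nb_params(cm, design, norm, robust=robust_dispersion)
    rng0 = replicate_rng(config, -1, 0)  # substream reserved for the original run
    res0 = run_de(method, cm, design, rng=rng0, threshold=threshold)
    grid = perturbation_grid(config)
    out: list[list] = []
    for j, a1 in enumerate(grid):
        row = []
        for m in range(config.M):
            rng = replicate_rng(config, j, m)
            pcm = perturb(cm, params, a1, rng)
            res = run_de(method, pcm, design, rng=rng, threshold=threshold)
            row.append(res if return_results else select(res))
        out.append(row)
    return (res0 if return_results else select(res0)), grid, out


def _curve_from_rhos(grid: np.ndarray, rhos: np.ndarray, s0_nonempty: bool, M: int) -> CorrelationCurve:
    anchor = 1.0 if s0_nonempty else 0.0
    ave = np.concatenate([[anchor], rhos.mean(axis=0)])
    alphas = np.concatenate([[0.0], grid])
    return CorrelationCurve(alphas=alphas, ave=ave, per_replicate=rhos, M=M)


def ave_curve(
    cm: CountMatrix,
    design: GroupDesign,
    method,
    config: PerturbationConfig,
    threshold: float = 0.05,
    norm_method: str = "median_ratio",
    robust_dispersion: bool = True,
) -> CorrelationCurve:
    """Ave(alpha1) over the perturbation grid, anchored at alpha1 = 0.

    The NB density is fitted once on the original data; s0 is the original
    selection; each grid point gets M independently perturbed datasets. If
    s0 is empty every rho is 0 (degenerate phi rule) and a warning is
    logged — this mirrors a method that cannot call any feature, which is
    maximal instability, not an error.
    """
    s0, grid, sels = _perturbation_selections(
        cm, design, method, config, threshold, norm_method, robust_dispersion
    )
    if s0.size == 0:
        logger.warning("original selection s0 is empty: curve is all-zero")
    rhos = np.array(
        [[phi_similarity(sels[j][m], s0) for j in range(len(grid))] for m in range(config.M)]
    )
    return _curve_from_rhos(grid, rhos, s0.size > 0, config.M)


def compute_aucor(
    cm: CountMatrix,
    design: GroupDesign,
    method,
    config: PerturbationConfig,
    threshold: float = 0.05,
    norm_method: str = "median_ratio",
    robust_dispersion: bool = True,
) -> AucorResult:
    """End-to-end AUCOR for one dataset and one DE method."""
    from .de import get_method

    if isinstance(method, str):
        method = get_method(method)
    curve = ave_curve(
        cm, design, method, config, threshold, norm_method, robust_dispersion
    )
    s0_size = 0
    # recover s0 size from the anchor convention: 1 iff non-empty
    if curve.ave[0] == 1.0:
        res0 = run_de(method, cm, design, rng=replicate_rng(config, -1, 0), threshold=threshold)
        s0_size = select(res0).size
    return AucorResult(
        aucor=aucor(curve),
        curve=curve,
        config=config,
        method_name=getattr(method, "name", "user_method"),
        threshold=threshold,
        s0_size=s0_size,
    )


def aucor_stratified(
    cm: CountMatrix,
    design: GroupDesign,
    method,
    config: PerturbationConfig,
    threshold: float = 0.05,
    norm_method: str = "median_ratio",
    robust_dispersion: bool = True,
) -> dict[str, AucorResult]:
    """AUCOR within four abundance strata split by average log2-CPM quartiles.

    DE always runs on the full matrix; the selection sets and the phi
    universe are then restricted to each stratum, so the multiple-testing
    universe is unchanged. Returns results keyed ``Q1`` (lowest abundance)
    to ``Q4`` (highest).
    """
    if cm.n_features < 8:
        raise ValueError("need G >= 8 features for non-degenerate quartiles")
    avg = cpm(cm, log2=True, prior_count=0.5).mean(axis=1)
    cuts = np.quantile(avg, [0.25, 0.5, 0.75])
    if len(np.unique(cuts)) < 3:
        raise ValueError(
            "degenerate log2-CPM quartiles (massive ties); stratify on a different basis"
        )
    bins = np.digitize(avg, cuts)  # 0..3, low to high abundance
    s0, grid, sels = _perturbation_selections(
        cm, design, method, config, threshold, norm_method, robust_dispersion
    )
    results: dict[str, AucorResult] = {}
    for q in range(4):
        mask = bins == q
        ids = [cm.feature_ids[i] for i in np.flatnonzero(mask)]
        s0q = SelectionSet(s0.indicator[mask], ids)
        rhos = np.array(
            [
                [
                    phi_similarity(SelectionSet(sels[j][m].indicator[mask], ids), s0q)
                    for j in range(len(grid))
                ]
                for m in range(config.M)
            ]
        )
        curve = _curve_from_rhos(grid, rhos, s0q.size > 0, config.M)
        results[f"Q{q+1}"] = AucorResult(
            aucor=aucor(curve),
            curve=curve,
            config=config,
            method_name=str(getattr(method, "name", method)),
            threshold=threshold,
            s0_size=s0q.size,
        )
    return results


def plot_curve(curve: CorrelationCurve, ax=None, **kwargs):
    """Scatter/line plot of Ave(alpha1) against alpha1."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.alphas, curve.ave, marker="o", **kwargs)
    ax.set_xlabel(r"perturbation size $\alpha_1$")
    ax.set_ylabel(r"Ave($\alpha_1$)")
    ax.set_ylim(-0.02, 1.02)
    return ax
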