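"""Validation harness: proxy ground-truth stability, validity, factor sweeps.

AUCOR estimates stability from a single dataset; its validation proxy is
the average pairwise selection-set similarity across R independent
datasets drawn from the same NB population. If AUCOR is informative, the
ranking of DE methods by AUCOR should agree with their ranking by the
proxy. Sensitivity/precision against the simulation truth cover the
validity side, and factor sweeps trace how stability responds to the study
design (replicate number, fold change, dispersion, outliers, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .de import SelectionSet, get_method, run_de, select
from .perturb import PerturbationConfig
from .simulate import SimulationConfig, TruthLabels, draw_counts, draw_truth
from .stability import (
    _curve_from_rhos,
    _perturbation_selections,
    aucor,
    compute_aucor,
    phi_similarity,
    proportion_intersection,
)

__all__ = [
    "ProxyStabilityResult",
    "FactorSweepResult",
    "proxy_stability",
    "rank_agreement",
    "sensitivity_precision",
    "factor_sweep",
    "FACTOR_NAMES",
]


@dataclass
class ProxyStabilityResult:
    """All-pairs similarity of selections across independent datasets."""

    pairwise_phi: np.ndarray
    pairwise_pi: np.ndarray
    mean_phi: float
    mean_pi: float
    method_name: str
    R: int


def proxy_stability(
    config: SimulationConfig,
    method,
    R: int = 20,
    threshold: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ProxyStabilityResult:
    """Proxy ground-truth stability from R independent datasets.

    The truth parameters (mean/dispersion pairs, DE flags, fold changes)
    are drawn once; R datasets add fresh NB noise. The method runs on each
    and all C(R, 2) pairwise phi and proportion-of-intersection values are
    returned.
    """
    if R < 2:
        raise ValueError("need R >= 2 datasets")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if isinstance(method, str):
        method = get_method(method)
    truth = draw_truth(config, rng)
    sets: list[SelectionSet] = []
    for _ in range(R):
        cm, design = draw_counts(truth, config.n_per_group, rng)
        res = run_de(method, cm, design, rng=rng, threshold=threshold)
        sets.append(select(res))
    phis, pis = [], []
    for a, b in combinations(sets, 2):
        phis.append(phi_similarity(a, b))
        pis.append(proportion_intersection(a, b))
    phis = np.asarray(phis)
    pis = np.asarray(pis)
    return ProxyStabilityResult(
        pairwise_phi=phis,
        pairwise_pi=pis,
        mean_phi=float(phis.mean()),
        mean_pi=float(pis.mean()),
        method_name=getattr(method, "name", "user_method"),
        R=R,
    )


def rank_agreement(
    aucor_values, proxy_values, method: str = "kendall"
) -> float:
    """Rank correlation between AUCOR and proxy stability across methods.

    Kendall tau-b by default (tie-corrected), Spearman rho optionally.
    """
    a = np.asarray(aucor_values, dtype=float)
    b = np.asarray(proxy_values, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need paired values for at least two methods")
    if method == "kendall":
        return float(stats.kendalltau(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError("rank correlation must be 'kendall' or 'spearman'")


def sensitivity_precision(
    sel: SelectionSet, truth: TruthLabels
) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and precision TP/(TP+FP) against the truth.

    Precision is 1 by convention when nothing is selected.
    """
    ind = sel.indicator
    if len(ind) != len(truth.is_de):
        raise ValueError("selection universe does not match truth length")
    tp = int((ind & truth.is_de).sum())
    n_sel = int(ind.sum())
    n_de = int(truth.is_de.sum())
    sens = tp / n_de if n_de else 0.0
    prec = tp / n_sel if n_sel else 1.0
    return sens, prec


FACTOR_NAMES = {
    "nSamp": "n_per_group",
    "gFeatures": "n_features",
    "pDE": "p_de",
    "mFoldChange": "fc_mean",
    "rDisp": "disp_ratio",
    "pUp": "p_up",
    "threshold": None,  # selection threshold, not a generator field
    "pOutlier": "p_outlier",
    "outlierMech": "outlier_mech",
}


@dataclass
class FactorSweepResult:
    """Tidy AUCOR/validity table for one swept factor."""

    factor_name: str
    levels: list
    table: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Mean AUCOR and its standard error per (level, method)."""
        g = self.table.groupby(["level", "method"], sort=False)["aucor"]
        out = g.agg(["mean", "sem", "count"]).reset_index()
        return out.rename(columns={"mean": "aucor_mean", "sem": "aucor_se", "count": "n_replicates"})


def factor_sweep(
    factor_name: str,
    levels,
    base: SimulationConfig,
    methods,
    pert: PerturbationConfig,
    replicates: int = 5,
    threshold: float = 0.05,
) -> FactorSweepResult:
    """Simulate, compute AUCOR and validity for each factor level.

    For every (level, replicate) a fresh dataset is simulated with a seed
    derived from the base seed; every method is scored on the same dataset.
    The ``threshold`` factor is special-cased: DE results for the original
    and all perturbed datasets are computed once per dataset and only the
    selection step is repeated per level.
    """
    if factor_name not in FACTOR_NAMES:
        raise ValueError(
            f"unknown factor {factor_name!r}; valid factors: {sorted(FACTOR_NAMES)}"
        )
    methods = [get_method(m) if isinstance(m, str) else m for m in methods]
    rows = []
    if factor_name == "threshold":
        for r in range(replicates):
            seed = int(np.random.SeedSequence(entropy=base.seed, spawn_key=(r,)).generate_state(1)[0] % (2**31))
            cfg = replace(base, seed=seed)
            cm, design, truth, _ = _simulate(cfg)
            for method in methods:
                p = replace(pert, seed=seed)
                res0, grid, results = _perturbation_selections(
                    cm, design, method, p, threshold=threshold, return_results=True
                )
                for level in levels:
                    s0 = select(res0, float(level))
                    rhos = np.array(
                        [
                            [
                                phi_similarity(select(results[j][m], float(level)), s0)
                                for j in range(len(grid))
                            ]
                            for m in range(p.M)
                        ]
                    )
                    curve = _curve_from_rhos(grid, rhos, s0.size > 0, p.M)
                    sens, prec = sensitivity_precision(s0, truth)
                    rows.append(
                        dict(
                            factor=factor_name,
                            level=level,
                            method=method.name,
                            replicate=r,
                            seed=seed,
                            aucor=aucor(curve),
                            sensitivity=sens,
                            precision=prec,
                        )
                    )
    else:
        field = FACTOR_NAMES[factor_name]
        for li, level in enumerate(levels):
            for r in range(replicates):
                seed = int(
                    np.random.SeedSequence(entropy=base.seed, spawn_key=(li, r)).generate_state(1)[0]
                    % (2**31)
                )
                kwargs = {field: level, "seed": seed}
                if factor_name == "pOutlier" and base.outlier_mech == "none":
                    kwargs["outlier_mech"] = "S"
                if factor_name == "outlierMech":
                    kwargs = {
                        "outlier_mech": "none" if level in ("N", "none") else level,
                        "seed": seed,
                    }
                    if kwargs["outlier_mech"] != "none" and base.p_outlier == 0:
                        kwargs["p_outlier"] = 0.1
                cfg = replace(base, **kwargs)
                cm, design, truth, _ = _simulate(cfg)
                for method in methods:
                    p = replace(pert, seed=seed)
                    result = compute_aucor(cm, design, method, p, threshold=threshold)
                    res0 = run_de(method, cm, design, rng=np.random.default_rng(seed), threshold=threshold)
                    sens, prec = sensitivity_precision(select(res0), truth)
                    rows.append(
                        dict(
                            factor=factor_name,
                            level=level,
                            method=method.name,
                            replicate=r,
                            seed=seed,
                            aucor=result.aucor,
                            sensitivity=sens,
                            precision=prec,
                        )
                    )
    return FactorSweepResult(factor_name=factor_name, levels=list(levels), table=pd.DataFrame(rows))


def _simulate(cfg: SimulationConfig):
    from .simulate import simulate_dataset

    return simulate_dataset(cfg)
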