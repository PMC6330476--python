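"""Differential-expression method contract, built-in methods, BH adjustment.

A DE method is any callable ``method(cm, design, rng) -> pvalues`` returning
one p-value per feature (NaN marks "not tested") and carrying a ``name``
attribute. ``run_de`` wraps the call, applies the universal expression
filter (features with zero counts everywhere are not tested), adjusts with
Benjamini-Hochberg, and ``select`` thresholds the adjusted values.

Built-ins: ``nb_wald`` (NB Wald z-test with trended dispersion),
``logcpm_welch`` (Welch t on log2-CPM), ``oracle`` (noisy truth scores, a
tunable stability reference), ``random_k`` (uniform random selection, the
instability reference) and ``constant_set`` (data-ignoring fixed set, the
perfect-stability reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .countdata import CountMatrix, GroupDesign, cpm, size_factors
from .nbmodel import estimate_dispersions, estimate_means

__all__ = [
    "DEResult",
    "SelectionSet",
    "bh_adjust",
    "run_de",
    "select",
    "nb_wald",
    "logcpm_welch",
    "oracle",
    "random_k",
    "constant_set",
    "get_method",
]

_P_SELECT = 1e-12  # pseudo p-value used by score-based reference methods


@dataclass
class DEResult:
    """Per-feature p-values and BH-adjusted p-values for one method run."""

    pvalues: np.ndarray
    padj: np.ndarray
    method_name: str
    threshold: float = 0.05
    feature_ids: list[str] | None = None

    def to_dataframe(self):
        import pandas as pd

        ids = self.feature_ids or [f"g{i+1}" for i in range(len(self.pvalues))]
        sel = np.where(np.isnan(self.padj), False, self.padj <= self.threshold)
        return pd.DataFrame(
            {"feature": ids, "pvalue": self.pvalues, "padj": self.padj, "selected": sel}
        )


@dataclass
class SelectionSet:
    """A selected feature subset as a boolean indicator over the universe."""

    indicator: np.ndarray
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=bool)

    @property
    def universe_size(self) -> int:
        return len(self.indicator)

    @property
    def size(self) -> int:
        return int(self.indicator.sum())

    @property
    def selected(self) -> set[str]:
        ids = self.feature_ids or [f"g{i+1}" for i in range(len(self.indicator))]
        return {ids[i] for i in np.flatnonzero(self.indicator)}


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries ("not tested") are excluded from the number of tests m and
    stay NaN in the output. Values outside [0, 1] raise.
    """
    p = np.asarray(pvalues, dtype=float)
    tested = ~np.isnan(p)
    if np.any((p[tested] < 0) | (p[tested] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    m = int(tested.sum())
    if m == 0:
        return out
    pt = p[tested]
    order = np.argsort(pt, kind="stable")
    ranked = pt[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[tested] = res
    return out


def run_de(
    method,
    cm: CountMatrix,
    design: GroupDesign,
    rng: np.random.Generator | None = None,
    threshold: float = 0.05,
) -> DEResult:
    """Run a DE method under the common contract and BH-adjust its p-values.

    ``method`` is a built-in name (see ``get_method``) or a callable
    ``(cm, design, rng) -> pvalues``. Features with zero counts in every
    sample are never tested. A wrong-length p-value vector is a contract
    violation.
    """
    if isinstance(method, str):
        method = get_method(method)
    if rng is None:
        rng = np.random.default_rng(0)
    if len(design.labels) != cm.n_samples:
        raise ValueError("design length does not match sample count")
    p = np.asarray(method(cm, design, rng), dtype=float)
    if p.shape != (cm.n_features,):
        raise ValueError(
            f"DE method {getattr(method, 'name', method)!r} returned "
            f"{p.shape} p-values for {cm.n_features} features (contract violation)"
        )
    p = p.copy()
    p[cm.counts.sum(axis=1) == 0] = np.nan  # uninformative features: not tested
    return DEResult(
        pvalues=p,
        padj=bh_adjust(p),
        method_name=getattr(method, "name", "user_method"),
        threshold=threshold,
        feature_ids=cm.feature_ids,
    )


def select(result: DEResult, threshold: float | None = None) -> SelectionSet:
    """Features with padj <= threshold; untested features are never selected."""
    t = result.threshold if threshold is None else threshold
    ind = np.where(np.isnan(result.padj), False, result.padj <= t)
    return SelectionSet(ind, result.feature_ids)


# ---------------------------------------------------------------------------
# built-in methods


def nb_wald(norm_method: str = "median_ratio"):
    """NB log-link Wald test on the group effect, trended dispersion.

    Per feature: the group log-fold effect is the log-ratio of normalized
    group means, its standard error comes from the NB Fisher information
    with working weights mu / (1 + phi * mu), and the dispersion is fixed
    at the trend-shrunk estimate from the NB model fit. Equivalent to a
    two-group NB GLM Wald z-test with known dispersion.
    """

    def method(cm: CountMatrix, design: GroupDesign, rng) -> np.ndarray:
        norm = size_factors(cm, norm_method)
        s = norm.size_factors
        phi_trend, _ = estimate_dispersions(cm, design, norm, robust=False)
        normed = cm.counts / s
        ga, gb = design.group_names
        ia, ib = design.group_indices[ga], design.group_indices[gb]
        floor = 0.125  # keeps the log-ratio finite for all-zero groups
        ma = np.maximum(normed[:, ia].mean(axis=1), floor)
        mb = np.maximum(normed[:, ib].mean(axis=1), floor)
        beta = np.log(mb) - np.log(ma)
        var = np.zeros(cm.n_features)
        for m_c, idx in ((ma, ia), (mb, ib)):
            mu_ci = m_c[:, None] * s[idx]
            w = mu_ci / (1.0 + phi_trend[:, None] * mu_ci)
            var += 1.0 / w.sum(axis=1)
        z = beta / np.sqrt(var)
        return 2 * stats.norm.sf(np.abs(z))

    method.name = "nb_wald"
    return method


def logcpm_welch(prior_count: float = 0.5):
    """Welch two-sample t-test on log2-CPM — a deliberately simple
    precision-weighted-linear-model stand-in. Zero-variance features get
    p = 1 so the selection set is always well-defined."""

    def method(cm: CountMatrix, design: GroupDesign, rng) -> np.ndarray:
        x = cpm(cm, log2=True, prior_count=prior_count)
        ga, gb = design.group_names
        a = x[:, design.group_indices[ga]]
        b = x[:, design.group_indices[gb]]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        p[~np.isfinite(p)] = 1.0  # zero variance in both groups
        return p

    method.name = "logcpm_welch"
    return method


def oracle(true_lfc: np.ndarray, noise_sd: float = 0.5, top_fraction: float = 0.1):
    """Noisy-truth reference: scores |true log2 fold change| + N(0, sd^2),
    selects the top ``top_fraction`` of features. Stability is tuned by
    ``noise_sd`` (0 = perfectly stable ranking)."""
    lfc = np.abs(np.asarray(true_lfc, dtype=float))

    def method(cm: CountMatrix, design: GroupDesign, rng: np.random.Generator) -> np.ndarray:
        if len(lfc) != cm.n_features:
            raise ValueError("oracle truth length does not match feature count")
        scores = lfc + rng.normal(0.0, noise_sd, size=len(lfc))
        k = max(1, int(round(top_fraction * len(lfc))))
        top = np.argsort(-scores, kind="stable")[:k]
        p = np.ones(len(lfc))
        p[top] = _P_SELECT
        return p

    method.name = f"oracle(sd={noise_sd})"
    return method


def random_k(k: int = 100):
    """Instability reference: selects k features uniformly at random."""

    def method(cm: CountMatrix, design: GroupDesign, rng: np.random.Generator) -> np.ndarray:
        if k > cm.n_features:
            raise ValueError("k exceeds the number of features")
        chosen = rng.choice(cm.n_features, size=k, replace=False)
        p = np.ones(cm.n_features)
        p[chosen] = _P_SELECT
        return p

    method.name = f"random_k({k})"
    return method


def constant_set(k: int = 100):
    """Perfect-stability reference: always selects the first k features."""

    def method(cm: CountMatrix, design: GroupDesign, rng) -> np.ndarray:
        p = np.ones(cm.n_features)
        p[: min(k, cm.n_features)] = _P_SELECT
        return p

    method.name = f"constant_set({k})"
    return method


_REGISTRY = {
    "nb_wald": nb_wald,
    "logcpm_welch": logcpm_welch,
    "random_k": random_k,
    "constant_set": constant_set,
}


def get_method(spec: str):
    """Resolve a method name like ``nb_wald`` or ``random_k:100``.

    The optional ``:arg`` suffix is passed to the factory (integer for
    random_k / constant_set).
    """
    name, _, arg = spec.partition(":")
    if name not in _REGISTRY:
        raise ValueError(
            f"unknown DE method {name!r}; built-ins: {sorted(_REGISTRY)}"
        )
    factory = _REGISTRY[name]
    if name in ("random_k", "constant_set"):
        return factory(int(arg)) if arg else factory()
    return factory()
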