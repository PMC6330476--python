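"""Negative-Binomial resampling density: per-cell means, per-feature dispersions.

The perturbation machinery resamples counts from NB(mu_gi, phi_g) with
variance mu + phi * mu^2. Means are condition-specific group means on the
normalized scale (so the differential signal survives resampling); the
dispersion estimator is a method-of-moments value shrunk 50/50 toward a
locally weighted mean-dispersion trend, with optional winsorization of each
feature at the 95th percentile of its own NB fit to blunt outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .countdata import CountMatrix, GroupDesign, NormalizationResult

__all__ = ["NBParams", "estimate_means", "estimate_dispersions", "estimate_nb_params", "sample_nb"]

MU_FLOOR = 1e-8
PHI_FLOOR = 1e-8
_TREND_OFFSET = 1e-4  # additive offset before log so zero dispersions stay finite


def _winsor_var_factor(q: float = 0.95) -> float:
    """Var(min(Z, z_q)) for standard normal Z: winsorized-variance consistency."""
    z = stats.norm.ppf(q)
    pdf = stats.norm.pdf(z)
    ew = -pdf + z * (1 - q)
    ew2 = q - z * pdf + z**2 * (1 - q)
    return ew2 - ew**2


_WINSOR_VAR_FACTOR = _winsor_var_factor(0.95)


@dataclass
class NBParams:
    """Fitted NB resampling density: mu (G x n), phi (G), and the trend knots.

    ``trend`` is a (K, 2) array of (log-mean, trend dispersion) knots from
    the locally weighted regression; it is kept for audit and for
    evaluating the trend at new means.
    """

    mu: np.ndarray
    phi: np.ndarray
    trend: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.mu.ndim != 2 or self.phi.shape != (self.mu.shape[0],):
            raise ValueError("mu must be G x n and phi length G")
        if np.any(self.mu < MU_FLOOR) or np.any(self.phi < 0):
            raise ValueError("mu must be >= floor and phi >= 0")

    def variance(self) -> np.ndarray:
        """Per-cell NB variance mu + phi * mu^2."""
        return self.mu + self.phi[:, None] * self.mu**2

    def trend_at(self, mean: np.ndarray) -> np.ndarray:
        """Evaluate the fitted mean->dispersion trend at given means."""
        if len(self.trend) == 0:
            return np.zeros_like(np.asarray(mean, dtype=float))
        logm = np.log(np.maximum(np.asarray(mean, dtype=float), MU_FLOOR))
        vals = np.interp(logm, self.trend[:, 0], self.trend[:, 1])
        return np.maximum(vals, 0.0)

    def to_tsv_bundle(self, directory: str | Path, feature_ids=None, sample_ids=None) -> None:
        """Serialize mu/phi/trend as a TSV bundle for audit and re-use."""
        import pandas as pd

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        G, n = self.mu.shape
        fids = feature_ids or [f"g{i+1}" for i in range(G)]
        sids = sample_ids or [f"s{i+1}" for i in range(n)]
        pd.DataFrame(self.mu, index=fids, columns=sids).to_csv(d / "mu.tsv", sep="\t")
        pd.DataFrame({"feature": fids, "phi": self.phi}).to_csv(
            d / "phi.tsv", sep="\t", index=False
        )
        pd.DataFrame(self.trend, columns=["log_mean", "phi_trend"]).to_csv(
            d / "trend.tsv", sep="\t", index=False
        )


def estimate_means(
    cm: CountMatrix, design: GroupDesign, norm: NormalizationResult
) -> np.ndarray:
    """Condition-specific fitted means mu_gi = q_g,c(i) * s_i.

    q_g,c is the mean of counts/s over samples in condition c. Means are
    floored at 1e-8 so the NB sampler stays defined for all-zero features
    (which then resample to zero almost surely).
    """
    s = norm.size_factors
    normed = cm.counts / s
    mu = np.empty(cm.shape, dtype=float)
    for _, idx in design.group_indices.items():
        q = normed[:, idx].mean(axis=1)
        mu[:, idx] = q[:, None] * s[idx]
    return np.maximum(mu, MU_FLOOR)


def _pooled_moments(
    normed: np.ndarray, design: GroupDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Overall mean and pooled within-group variance of normalized counts."""
    mbar = normed.mean(axis=1)
    ss = np.zeros(normed.shape[0])
    df = 0
    for _, idx in design.group_indices.items():
        if len(idx) >= 2:
            ss += normed[:, idx].var(axis=1, ddof=1) * (len(idx) - 1)
            df += len(idx) - 1
    if df == 0:
        raise ValueError("dispersion not estimable: no condition has >= 2 replicates")
    return mbar, ss / df


def estimate_dispersions(
    cm: CountMatrix,
    design: GroupDesign,
    norm: NormalizationResult,
    robust: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature dispersions with a robust mean-dispersion trend.

    Steps: (1) method-of-moments phi = max(0, (s2 - m) / m^2) from pooled
    within-group variance of normalized counts; (2) lowess of
    log(phi + 1e-4) on log(mean) over features with mean > 1 gives the
    trend; (3) final phi = max(0.5 * MoM + 0.5 * trend(mean), 1e-8). With
    ``robust`` each feature's counts are first winsorized at the 95th
    percentile of its provisional NB fit, damping the influence of
    outlier counts on the variance.

    Returns ``(phi, trend_knots)``.
    """
    s = norm.size_factors
    normed = cm.counts / s
    winsorized = False
    if robust:
        # caps come from the cross-feature trend dispersion, not the
        # feature's own MoM value: an outlier inflates its feature's MoM
        # (raising its own cap and escaping the clip) but barely moves the
        # trend, so trend-based caps stay resistant to the contamination
        mbar0, s2_0 = _pooled_moments(normed, design)
        phi_mom0 = np.maximum(0.0, (s2_0 - mbar0) / np.maximum(mbar0, MU_FLOOR) ** 2)
        trend0 = _fit_trend(mbar0, phi_mom0)
        phi0 = np.maximum(_eval_trend(trend0, mbar0), PHI_FLOOR)
        # winsorize on the raw-count scale at each cell's NB 95th percentile
        mu_cell = np.maximum(mbar0[:, None] * s[None, :], MU_FLOOR)
        caps = _nb_quantile(0.95, mu_cell, phi0[:, None])
        normed = np.minimum(cm.counts, caps) / s
        winsorized = True
    mbar, s2 = _pooled_moments(normed, design)
    if winsorized:
        # consistency correction: one-sided capping at the 95th percentile
        # clips ~5% of clean mass and deflates the variance by the
        # normal-theory factor Var(min(Z, z95)) ~= 0.915
        s2 = s2 / _WINSOR_VAR_FACTOR
    phi_mom = np.maximum(0.0, (s2 - mbar) / np.maximum(mbar, MU_FLOOR) ** 2)
    trend = _fit_trend(mbar, phi_mom)
    trend_vals = _eval_trend(trend, mbar)
    phi = np.maximum(0.5 * phi_mom + 0.5 * trend_vals, PHI_FLOOR)
    return phi, trend


def _fit_trend(mbar: np.ndarray, phi_mom: np.ndarray) -> np.ndarray:
    """Lowess trend of log(phi + offset) on log(mean), features with mean > 1."""
    keep = mbar > 1
    if keep.sum() < 10:
        # too few informative features for a local fit: flat trend at the median
        med = float(np.median(phi_mom[keep])) if keep.any() else 0.0
        return np.array([[0.0, med], [20.0, med]])
    x = np.log(mbar[keep])
    y = np.log(phi_mom[keep] + _TREND_OFFSET)
    fitted = lowess(y, x, frac=0.4, it=0, return_sorted=True)
    # collapse duplicate x (ties) and convert back to dispersion scale
    xs, idx = np.unique(fitted[:, 0], return_index=True)
    ys = np.exp(fitted[idx, 1]) - _TREND_OFFSET
    return np.column_stack([xs, np.maximum(ys, 0.0)])


def _eval_trend(trend: np.ndarray, mean: np.ndarray) -> np.ndarray:
    logm = np.log(np.maximum(mean, MU_FLOOR))
    return np.maximum(np.interp(logm, trend[:, 0], trend[:, 1]), 0.0)


def estimate_nb_params(
    cm: CountMatrix,
    design: GroupDesign,
    norm: NormalizationResult,
    robust: bool = True,
) -> NBParams:
    """Convenience: fit means and dispersions into one NBParams."""
    mu = estimate_means(cm, design, norm)
    phi, trend = estimate_dispersions(cm, design, norm, robust=robust)
    return NBParams(mu=mu, phi=phi, trend=trend)


def _nb_quantile(q: float, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Quantile of NB(mu, phi); Poisson where phi == 0."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape)
    pois = phi <= 0
    if pois.any():
        out[pois] = stats.poisson.ppf(q, mu[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        out[~pois] = stats.nbinom.ppf(q, r, r / (r + mu[~pois]))
    return out


def sample_nb(mu, phi, rng: np.random.Generator):
    """Draw NB counts with mean ``mu`` and variance ``mu + phi * mu^2``.

    phi = 0 degenerates to Poisson(mu). ``mu`` and ``phi`` broadcast;
    the return matches the broadcast shape (scalar in, scalar out).
    """
    mu_a = np.asarray(mu, dtype=float)
    phi_a = np.asarray(phi, dtype=float)
    if np.any(~np.isfinite(mu_a)) or np.any(~np.isfinite(phi_a)):
        raise ValueError("mu and phi must be finite")
    if np.any(mu_a <= 0) or np.any(phi_a < 0):
        raise ValueError("require mu > 0 and phi >= 0")
    mu_b, phi_b = np.broadcast_arrays(mu_a, phi_a)
    out = np.empty(mu_b.shape, dtype=np.int64)
    pois = phi_b == 0
    if pois.any():
        out[pois] = rng.poisson(mu_b[pois])
    over = ~pois
    if over.any():
        r = 1.0 / phi_b[over]
        out[over] = rng.negative_binomial(r, r / (r + mu_b[over]))
    if np.isscalar(mu) and np.isscalar(phi):
        return int(out)
    return out
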