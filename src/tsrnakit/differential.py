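"""Count normalization and negative-binomial differential abundance.

Normalization is the median-of-ratios estimator: each sample's size factor
is the median, over features, of the ratio of its count to the feature's
geometric mean across samples, rescaled so the factors have unit geometric
mean.  Differential testing models counts as negative binomial with
variance mu + alpha*mu^2.  Per-feature dispersions are estimated by the
method of moments on normalized counts, shrunk toward a fitted
mean-dispersion trend (gamma-family regression of dispersion on mean,
alpha(mu) = a0 + a1/mu), and the two-group comparison uses the conditional
exact NB test (the Robinson-Smyth construction: the distribution of one
group's sum given the total is free of the mean) for small designs, or a
Wald test on the log scale for larger ones.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .containers import CountMatrix

__all__ = [
    "size_factors",
    "normalize_counts",
    "nb_test",
    "bh_adjust",
    "bonferroni_adjust",
]

MIN_DISPERSION = 1e-8
#: weight of the fitted trend when moderating per-feature dispersions,
#: expressed as prior degrees of freedom (edgeR-style weighted average).
PRIOR_DF = 10.0


def size_factors(raw: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to unit geometric mean."""
    if raw.normalized:
        raise ValueError("size factors are estimated from raw counts")
    counts = raw.data.values.astype(float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    all_pos = np.isfinite(logc).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; supply a "
            "pseudo-reference or filter samples"
        )
    log_geomean = logc[all_pos].mean(axis=1)
    log_ratios = logc[all_pos] - log_geomean[:, None]
    log_sf = np.median(log_ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # unit geometric mean
    return pd.Series(np.exp(log_sf), index=raw.data.columns, name="size_factor")


def normalize_counts(raw: CountMatrix, sf: pd.Series | None = None) -> CountMatrix:
    if sf is None:
        sf = size_factors(raw)
    data = raw.data.div(sf, axis=1)
    return CountMatrix(data=data, normalized=True)


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _fit_dispersion_trend(mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Gamma-family regression alpha(mu) = a0 + a1/mu, evaluated at mu.

    Falls back to the median positive dispersion when the regression is
    degenerate (few usable features, or nonpositive coefficients).
    """
    import statsmodels.api as sm

    ok = (mu > 0) & (disp > 10 * MIN_DISPERSION) & np.isfinite(disp)
    fallback = float(np.median(disp[ok])) if ok.sum() else 10 * MIN_DISPERSION
    trend = np.full_like(mu, fallback, dtype=float)
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(
                    disp[ok], X, family=sm.families.Gamma(sm.families.links.Identity())
                ).fit(start_params=[fallback, 1.0])
            a0, a1 = fit.params
            if a0 > 0 and np.isfinite(a0) and np.isfinite(a1):
                cand = a0 + np.maximum(a1, 0.0) / np.maximum(mu, 1e-8)
                trend = np.where(mu > 0, cand, fallback)
        except Exception:
            pass
    return np.maximum(trend, MIN_DISPERSION)


def _estimate_dispersions(
    norm_counts: np.ndarray, groups: np.ndarray, sf: np.ndarray
) -> np.ndarray:
    """Trend-moderated method-of-moments dispersions per feature."""
    labels = np.unique(groups)
    n = norm_counts.shape[1]
    mu = norm_counts.mean(axis=1)
    # pooled within-group variance of normalized counts
    ss = np.zeros(norm_counts.shape[0])
    df = 0
    for g in labels:
        sel = groups == g
        if sel.sum() > 1:
            ss += norm_counts[:, sel].var(axis=1, ddof=1) * (sel.sum() - 1)
            df += sel.sum() - 1
    if df == 0:
        raise ValueError("need replication in at least one group")
    v = ss / df
    xi = float(np.mean(1.0 / sf))  # Poisson part on the normalized scale
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_disp = (v - xi * mu) / mu**2
    raw_disp = np.where(np.isfinite(raw_disp), raw_disp, 0.0)
    trend = _fit_dispersion_trend(mu, np.maximum(raw_disp, MIN_DISPERSION))
    moderated = (df * np.maximum(raw_disp, 0.0) + PRIOR_DF * trend) / (
        df + PRIOR_DF
    )
    return np.maximum(moderated, MIN_DISPERSION)


def _exact_nb_pvalue(sa: int, sb: int, na: int, nb: int, disp: float) -> float:
    """Two-sided conditional exact NB p-value.

    Group sums of iid NB(mu, alpha) counts are NB with size n/alpha; given
    the total s = sa + sb, the conditional probability of a split (a, s-a)
    does not depend on mu, so the two-sided p-value is the summed
    conditional probability of all splits at most as likely as the one
    observed (with a 1e-7 relative tolerance on ties).
    """
    s = sa + sb
    if s == 0:
        return 1.0
    ra = na / disp
    rb = nb / disp
    a = np.arange(s + 1)
    logp = (
        gammaln(a + ra)
        - gammaln(a + 1)
        + gammaln(s - a + rb)
        - gammaln(s - a + 1)
    )
    logp -= logsumexp(logp)
    cutoff = logp[sa] + np.log1p(1e-7)
    return float(min(1.0, np.exp(logsumexp(logp[logp <= cutoff]))))


def nb_test(
    raw: CountMatrix,
    sf: pd.Series | Mapping[str, float] | None,
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Two-group negative-binomial differential abundance test.

    ``groups`` maps sample id to one of exactly two group labels.  Returns
    a frame with baseMean per group, log2 fold change (second group over
    first, labels in sorted order), p-value, BH-adjusted p-value and the
    test variant used.
    """
    if raw.normalized:
        raise ValueError("nb_test expects raw counts plus size factors")
    samples = list(raw.data.columns)
    if sf is None:
        sf = size_factors(raw)
    sf_arr = np.array([float(sf[s]) for s in samples])
    glabels = np.array([groups[s] for s in samples])
    uniq = np.unique(glabels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    ga, gb = uniq
    sel_a = glabels == ga
    sel_b = glabels == gb
    counts = raw.data.values.astype(float)
    if counts[:, sel_a].sum() == 0 or counts[:, sel_b].sum() == 0:
        raise ValueError("one group has an all-zero library")

    norm_counts = counts / sf_arr
    disp = _estimate_dispersions(norm_counts, glabels, sf_arr)
    # common-scale pseudo-counts: normalized counts are already on the
    # geometric-mean library scale (size factors have unit geomean)
    pseudo = np.floor(norm_counts + 0.5).astype(np.int64)

    na = int(sel_a.sum())
    nb = int(sel_b.sum())
    mu_a = norm_counts[:, sel_a].mean(axis=1)
    mu_b = norm_counts[:, sel_b].mean(axis=1)

    use_exact = max(na, nb) <= 5
    pvals = np.empty(counts.shape[0])
    if use_exact:
        sa = pseudo[:, sel_a].sum(axis=1)
        sb = pseudo[:, sel_b].sum(axis=1)
        for i in range(counts.shape[0]):
            pvals[i] = _exact_nb_pvalue(
                int(sa[i]), int(sb[i]), na, nb, float(disp[i])
            )
        method = "nb-exact"
    else:
        eps = 1e-8
        var_log = (1.0 / na) * (1.0 / np.maximum(mu_a, eps) + disp) + (
            1.0 / nb
        ) * (1.0 / np.maximum(mu_b, eps) + disp)
        z = (np.log(mu_b + eps) - np.log(mu_a + eps)) / np.sqrt(var_log)
        pvals = 2 * norm.sf(np.abs(z))
        method = "nb-wald"

    fc_a = np.where(mu_a == 0, 0.5, mu_a)
    fc_b = np.where(mu_b == 0, 0.5, mu_b)
    log2fc = np.log2(fc_b / fc_a)
    return pd.DataFrame(
        {
            f"baseMean_{ga}": mu_a,
            f"baseMean_{gb}": mu_b,
            "log2FC": log2fc,
            "dispersion": disp,
            "pval": pvals,
            "padj": bh_adjust(pvals),
            "method": method,
        },
        index=raw.data.index,
    )
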