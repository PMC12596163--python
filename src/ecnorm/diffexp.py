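"""Negative-binomial two-group differential expression.

Counts are modelled as NB(mu_ij, alpha_i) with Var = mu + alpha * mu^2 and
log-linear mean mu_ij = s_j * exp(beta0_i + beta1_i * x_j), where s_j is
the sample's size factor and x_j in {0, 1} indicates the non-reference
group.  The pipeline is:

1. per-gene method-of-moments dispersion, pooled across the two groups,
   optionally shrunk toward a fitted mean-dispersion trend
   alpha(mu) = a0 + a1 / mu;
2. a per-gene NB GLM fit by iteratively reweighted least squares with the
   dispersion held fixed;
3. a Wald test of the group coefficient, with the standard error taken
   from the inverse observed Fisher information at the optimum;
4. Benjamini-Hochberg adjustment of the Wald p-values.

log2 fold change is beta1 / ln 2 (non-reference vs reference group).  No
fold-change shrinkage is applied: the downstream endogenous-control filter
thresholds |log2FC| at values as small as 0.02, which shrinkage would
distort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import CountMatrix, SampleMetadata
from .normalization import SizeFactors

__all__ = [
    "DispersionEstimates",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
]

_LN2 = np.log(2.0)
_MIN_DISP = 1e-8  # floor protecting log() in shrinkage and initialization
_MAX_ITER = 100
_TOL = 1e-8


@dataclass(frozen=True)
class DispersionEstimates:
    """Per-gene NB dispersions (Var = mu + alpha * mu^2).

    ``alpha_raw`` is the gene-wise method-of-moments estimate;
    ``alpha_trend`` the fitted trend value at the gene's mean (NaN when
    shrinkage is disabled); ``alpha`` the value used by the Wald test
    (equal to ``alpha_raw`` when shrinkage is disabled).
    """

    gene_ids: tuple[str, ...]
    alpha: np.ndarray
    alpha_raw: np.ndarray
    alpha_trend: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        for name in ("alpha", "alpha_raw", "alpha_trend"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if np.any(self.alpha < 0) or not np.all(np.isfinite(self.alpha)):
            raise ValidationError("dispersions must be finite and >= 0")


def _group_masks(meta: SampleMetadata) -> tuple[np.ndarray, np.ndarray]:
    x = meta.indicator
    return x == 0, x == 1


def _fit_trend(alpha_raw: np.ndarray, base_mean: np.ndarray) -> np.ndarray:
    """Robust fit of alpha(mu) = a0 + a1/mu on genes with alpha_raw > 0."""
    import statsmodels.api as sm

    pos = (alpha_raw > 0) & (base_mean > 0) & np.isfinite(alpha_raw)
    trend = np.full_like(alpha_raw, _MIN_DISP)
    ok = base_mean > 0
    if pos.sum() < 10:
        # too few informative genes for a regression: flat trend
        level = np.median(alpha_raw[pos]) if pos.any() else _MIN_DISP
        trend[ok] = max(level, _MIN_DISP)
        return trend
    exog = sm.add_constant(1.0 / base_mean[pos])
    try:
        fit = sm.RLM(alpha_raw[pos], exog, M=sm.robust.norms.HuberT()).fit()
        a0, a1 = fit.params
    except Exception:  # singular / non-convergent robust fit
        a0, a1 = float(np.median(alpha_raw[pos])), 0.0
    trend[ok] = np.clip(a0 + a1 / base_mean[ok], _MIN_DISP, None)
    return trend


def estimate_dispersions(cm: CountMatrix, sf: SizeFactors, meta: SampleMetadata,
                         shrink: bool = True) -> DispersionEstimates:
    """Pooled method-of-moments dispersions with optional trend shrinkage.

    With group-wise means mu_g and variances s2_g of normalized counts and
    weights w_g = (n_g - 1)/(n - 2), the gene-wise estimate is
    ``alpha_raw = max(0, sum_g w_g * (s2_g - mu_g) / mu_g^2)``.  With
    ``shrink=True`` the final dispersion is the geometric interpolation
    ``exp(0.5*log(alpha_trend) + 0.5*log(max(alpha_raw, 1e-8)))``.
    """
    meta = meta.aligned_to(cm.sample_ids)
    mask_a, mask_b = _group_masks(meta)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 2 or n_b < 2:
        raise ValidationError(
            "each group needs at least 2 samples to estimate within-group "
            f"variance (got {n_a} and {n_b})"
        )
    n = n_a + n_b
    norm = cm.counts.astype(float) / sf.factors[None, :]
    acc = np.zeros(cm.n_genes)
    for mask, n_g in ((mask_a, n_a), (mask_b, n_b)):
        mu = norm[:, mask].mean(axis=1)
        var = norm[:, mask].var(axis=1, ddof=1)
        w = (n_g - 1) / (n - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(mu > 0, (var - mu) / np.square(mu), 0.0)
        acc += w * term
    alpha_raw = np.maximum(acc, 0.0)
    if shrink:
        base_mean = norm.mean(axis=1)
        alpha_trend = _fit_trend(alpha_raw, base_mean)
        alpha = np.exp(0.5 * np.log(alpha_trend)
                       + 0.5 * np.log(np.maximum(alpha_raw, _MIN_DISP)))
    else:
        alpha_trend = np.full(cm.n_genes, np.nan)
        alpha = alpha_raw.copy()
    return DispersionEstimates(gene_ids=cm.gene_ids, alpha=alpha,
                               alpha_raw=alpha_raw, alpha_trend=alpha_trend)


def nb_wald_test(cm: CountMatrix, sf: SizeFactors, disp: DispersionEstimates,
                 meta: SampleMetadata) -> pd.DataFrame:
    """Per-gene NB GLM Wald test of the two-group coefficient.

    Returns a DataFrame with columns ``gene_id, base_mean, log2fc, se,
    wald_stat, pvalue, fdr, converged``.  Genes that are all-zero in both
    groups are untestable and reported as NA; genes whose fit does not
    converge within 100 iterations (e.g. one group entirely zero, so the
    fold change diverges) keep their last log2fc iterate but get NA
    se/pvalue/fdr and ``converged=False``.
    """
    meta = meta.aligned_to(cm.sample_ids)
    if tuple(disp.gene_ids) != tuple(cm.gene_ids):
        raise ValidationError("dispersion gene ids do not match count matrix")
    if tuple(sf.sample_ids) != tuple(cm.sample_ids):
        raise ValidationError("size factor samples do not match count matrix")
    mask_a, mask_b = _group_masks(meta)
    if mask_a.sum() < 1 or mask_b.sum() < 1:
        raise ValidationError("both groups must be non-empty")

    y = cm.counts.astype(float)
    n_genes = cm.n_genes
    s = sf.factors
    log_s = np.log(s)[None, :]
    # no dispersion floor here: every weight denominator is 1 + alpha*mu >= 1,
    # and flooring alpha would bias the fit away from the Poisson limit
    a = disp.alpha[:, None]
    norm = y / s[None, :]
    base_mean = norm.mean(axis=1)

    testable = y.sum(axis=1) > 0
    mean_a = norm[:, mask_a].mean(axis=1)
    mean_b = norm[:, mask_b].mean(axis=1)
    b0 = np.log(np.maximum(base_mean, _MIN_DISP))
    b1 = np.log(np.maximum(mean_b, _MIN_DISP)) - np.log(np.maximum(mean_a, _MIN_DISP))

    converged = np.zeros(n_genes, dtype=bool)
    active = np.flatnonzero(testable)
    for _ in range(_MAX_ITER):
        if active.size == 0:
            break
        eta = b0[active, None] + b1[active, None] * mask_b[None, :] + log_s
        mu = np.exp(np.clip(eta, -500.0, 500.0))
        w = mu / (1.0 + a[active] * mu)
        z = (eta - log_s) + (y[active] - mu) / mu
        sw_a = w[:, mask_a].sum(axis=1)
        sw_b = w[:, mask_b].sum(axis=1)
        swz_a = (w[:, mask_a] * z[:, mask_a]).sum(axis=1)
        swz_b = (w[:, mask_b] * z[:, mask_b]).sum(axis=1)
        ok = (sw_a > 0) & (sw_b > 0)
        # saturated two-group design: the WLS solution is the pair of
        # weighted group means of the working response
        new_b0 = np.where(ok, swz_a / np.maximum(sw_a, 1e-300), b0[active])
        new_b1 = np.where(ok, swz_b / np.maximum(sw_b, 1e-300) - new_b0, b1[active])
        finite = np.isfinite(new_b0) & np.isfinite(new_b1)
        delta = np.maximum(np.abs(new_b0 - b0[active]), np.abs(new_b1 - b1[active]))
        b0[active] = np.where(finite, new_b0, b0[active])
        b1[active] = np.where(finite, new_b1, b1[active])
        done = finite & ok & (delta < _TOL)
        converged[active[done]] = True
        dead = ~(finite & ok)  # numerically broken fits: stop iterating
        active = active[~(done | dead)]

    # observed Fisher information at the optimum
    eta = b0[:, None] + b1[:, None] * mask_b[None, :] + log_s
    mu = np.exp(np.clip(eta, -500.0, 500.0))
    w_obs = mu * (1.0 + a * y) / np.square(1.0 + a * mu)
    i_a = w_obs[:, mask_a].sum(axis=1)
    i_b = w_obs[:, mask_b].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = 1.0 / i_a + 1.0 / i_b

    valid = converged & (var_b1 > 0) & np.isfinite(var_b1)
    se = np.where(valid, np.sqrt(np.where(valid, var_b1, 1.0)), np.nan) / _LN2
    log2fc = np.where(testable, b1 / _LN2, np.nan)
    wald = np.where(valid, (b1 / _LN2) / se, np.nan)
    pvalue = np.where(valid, 2.0 * stats.norm.sf(np.abs(wald)), np.nan)
    fdr = bh_adjust(pvalue)

    return pd.DataFrame({
        "gene_id": list(cm.gene_ids),
        "base_mean": base_mean,
        "log2fc": log2fc,
        "se": se,
        "wald_stat": wald,
        "pvalue": pvalue,
        "fdr": fdr,
        "converged": converged,
    })


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up over the non-NA entries.

    NA in, NA out; m = number of non-NA p-values.  Values outside [0, 1]
    raise :class:`ValidationError`.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = ~np.isnan(p)
    if finite.any():
        vals = p[finite]
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError("p-values must lie in [0, 1]")
        out[finite] = multipletests(vals, method="fdr_bh")[1]
    return out
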