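"""Horizontal-pleiotropy gatekeeping: Egger-intercept screen and MR-PRESSO.

MR-PRESSO (pleiotropy residual sum of squares and outlier test) compares the
observed weighted residual sum of squares of leave-one-out IVW fits against
its parametric-simulation null: a significant global test indicates
horizontal pleiotropy somewhere in the instrument set, per-SNP empirical
p-values locate the offending instruments, and the distortion test asks
whether removing them materially moves the IVW estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientSnpsError
from .mr_core import MREstimate, PleiotropyTest, ivw
from .summary_data import AnalysisConfig, HarmonizedSet


def egger_intercept_screen(intercept_test: PleiotropyTest,
                           alpha: float = 0.05) -> bool:
    """True when the exposure-outcome pair should be excluded for pleiotropy.

    Strict inequality: an intercept p-value exactly equal to ``alpha`` is
    retained.
    """
    return intercept_test.pval < alpha


@dataclass
class PressoResult:
    """Outcome of the MR-PRESSO global, outlier, and distortion tests."""

    global_rss: float
    global_pval: float
    outlier_pvals: dict  # snp -> Bonferroni-corrected empirical p
    outlier_ids: list
    distortion_pval: float | None  # None when no outliers were flagged
    beta_corrected: MREstimate | None


def _loo_ivw_betas(bx, by, w):
    """Leave-one-out IVW slope for each SNP, vectorized."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    config: AnalysisConfig | None = None,
) -> PressoResult:
    """Run the MR-PRESSO global, outlier and distortion tests.

    Per SNP j the residual against its leave-one-out IVW fit is
    ``rss_j = w_j (beta_out,j - beta_loo(-j) * beta_exp,j)^2`` with
    ``w_j = 1/se_out,j^2``; the global statistic is their sum.  ``n_sim``
    parametric datasets (beta_exp* ~ N(beta_exp, se_exp), beta_out* ~
    N(beta_loo(-j)*beta_exp, se_out)) give plus-one empirical p-values, so no
    p can fall below 1/(n_sim+1).  Per-SNP p-values are Bonferroni-corrected
    by the number of SNPs; flagged outliers are removed and IVW is recomputed
    (``beta_corrected``).  The distortion p compares the with/without-outlier
    IVW contrast against the same contrast under random pseudo-outlier sets
    of equal size.
    """
    if len(h) < 4:
        raise InsufficientSnpsError("MR-PRESSO needs at least 4 SNPs")
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    p = h.pairs
    bx = p["beta_exp"].to_numpy(float)
    sx = p["se_exp"].to_numpy(float)
    by = p["beta_out"].to_numpy(float)
    so = p["se_out"].to_numpy(float)
    snps = p["snp"].tolist()
    n = len(bx)
    w = 1.0 / so**2

    beta_loo = _loo_ivw_betas(bx, by, w)
    rss_j = w * (by - beta_loo * bx) ** 2
    global_rss = float(rss_j.sum())

    # parametric simulation under the no-pleiotropy expectation
    bx_s = rng.normal(bx, sx, size=(n_sim, n))
    by_s = rng.normal(beta_loo * bx, so, size=(n_sim, n))
    sxy = np.sum(w * bx_s * by_s, axis=1, keepdims=True)
    sxx = np.sum(w * bx_s**2, axis=1, keepdims=True)
    beta_loo_s = (sxy - w * bx_s * by_s) / (sxx - w * bx_s**2)
    rss_s = w * (by_s - beta_loo_s * bx_s) ** 2

    global_pval = float((1 + np.sum(rss_s.sum(axis=1) >= global_rss)) / (n_sim + 1))
    p_raw = (1 + np.sum(rss_s >= rss_j, axis=0)) / (n_sim + 1)
    p_corr = np.minimum(1.0, p_raw * n)
    outlier_mask = p_corr < outlier_alpha
    outlier_ids = [s for s, m in zip(snps, outlier_mask) if m]

    beta_corrected = None
    distortion_pval = None
    if outlier_ids:
        h_clean = h.drop_snps(outlier_ids, "presso_outliers_removed")
        beta_corrected, _ = ivw(h_clean, config)
        beta_all, _ = ivw(h, config)
        d_obs = abs(beta_all.beta - beta_corrected.beta)
        k = len(outlier_ids)
        d_sim = np.empty(n_sim)
        for i in range(n_sim):
            idx = rng.choice(n, size=k, replace=False)
            keep = np.ones(n, dtype=bool)
            keep[idx] = False
            b = np.sum(w[keep] * bx[keep] * by[keep]) / np.sum(w[keep] * bx[keep] ** 2)
            d_sim[i] = abs(beta_all.beta - b)
        distortion_pval = float((1 + np.sum(d_sim >= d_obs)) / (n_sim + 1))

    return PressoResult(
        global_rss=global_rss,
        global_pval=global_pval,
        outlier_pvals=dict(zip(snps, p_corr.astype(float))),
        outlier_ids=outlier_ids,
        distortion_pval=distortion_pval,
        beta_corrected=beta_corrected,
    )
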