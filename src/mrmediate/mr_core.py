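"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a :class:`~mrmediate.summary_data.HarmonizedSet` of
per-SNP (beta_exp, se_exp, beta_out, se_out) pairs.  The inverse-variance
weighted (IVW) estimator is the primary method; Cochran's Q decides between
its fixed-effect and multiplicative random-effects flavours.  MR-Egger adds a
free intercept as a test for directional horizontal pleiotropy, and the
weighted median is robust to up to half the weight coming from invalid
instruments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInstrumentError, EmptyInputError, InsufficientSnpsError
from .summary_data import AnalysisConfig, HarmonizedSet

Z95 = 1.96


@dataclass
class MREstimate:
    """A causal-effect estimate on the outcome scale."""

    method: str  # wald | ivw_fixed | ivw_random | egger | weighted_median
    beta: float
    se: float
    pval: float
    n_snp: int
    or_: float | None = None
    lci95: float | None = None
    uci95: float | None = None

    def with_or(self) -> "MREstimate":
        """Return a copy with odds-ratio fields filled (binary outcomes)."""
        o, lo, hi = beta_to_or(self.beta, self.se)
        return MREstimate(self.method, self.beta, self.se, self.pval,
                          self.n_snp, o, lo, hi)


@dataclass
class HeterogeneityTest:
    """Cochran's Q heterogeneity test across per-SNP Wald ratios."""

    q_stat: float
    df: int
    pval: float


@dataclass
class PleiotropyTest:
    """MR-Egger intercept test for directional horizontal pleiotropy."""

    intercept: float
    se: float
    pval: float
    alpha: float = 0.05
    flagged: bool = False

    def __post_init__(self) -> None:
        self.flagged = self.pval < self.alpha


def _arrays(h: HarmonizedSet):
    p = h.pairs
    return (p["beta_exp"].to_numpy(float), p["se_exp"].to_numpy(float),
            p["beta_out"].to_numpy(float), p["se_out"].to_numpy(float))


def _two_sided_normal_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wald_ratio(beta_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-SNP Wald ratio: beta_out / beta_exp with first-order SE."""
    if beta_exp == 0:
        raise DegenerateInstrumentError("Wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate("wald", beta, se, _two_sided_normal_p(beta / se), 1)


def cochran_q(h: HarmonizedSet, beta_ivw: float) -> HeterogeneityTest:
    """Cochran's Q of the per-SNP Wald ratios around ``beta_ivw``.

    Q = sum_j (|beta_exp,j| / se_out,j)^2 (ratio_j - beta_ivw)^2, compared to
    a chi-square with n_snp - 1 degrees of freedom.
    """
    if len(h) < 2:
        raise InsufficientSnpsError("Cochran's Q needs at least 2 SNPs")
    bx, _, by, so = _arrays(h)
    ratios = by / bx
    se_ratio = so / np.abs(bx)
    q = float(np.sum((ratios - beta_ivw) ** 2 / se_ratio**2))
    df = len(h) - 1
    return HeterogeneityTest(q, df, float(stats.chi2.sf(q, df)))


def ivw(h: HarmonizedSet, config: AnalysisConfig | None = None
        ) -> tuple[MREstimate, HeterogeneityTest | None]:
    """Inverse-variance weighted estimate with Q-driven fixed/random choice.

    Weighted least squares of beta_out on beta_exp through the origin with
    weights 1/se_out^2.  If Cochran's Q rejects homogeneity at
    ``q_test_alpha`` the standard error is inflated by sqrt(Q/df) (floored at
    1): the multiplicative random-effects model.  A single SNP falls back to
    the Wald ratio.
    """
    config = config or AnalysisConfig()
    if len(h) == 0:
        raise EmptyInputError("cannot run IVW on an empty harmonized set")
    if len(h) == 1:
        row = h.pairs.iloc[0]
        est = wald_ratio(row["beta_exp"], row["beta_out"], row["se_out"])
        return est, None
    bx, _, by, so = _arrays(h)
    w = 1.0 / so**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = denom**-0.5
    het = cochran_q(h, beta)
    method = "ivw_fixed"
    if het.pval < config.q_test_alpha:
        method = "ivw_random"
        se *= max(1.0, np.sqrt(het.q_stat / het.df))
    return MREstimate(method, beta, se, _two_sided_normal_p(beta / se), len(h)), het


def egger(h: HarmonizedSet) -> tuple[MREstimate, PleiotropyTest]:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Pairs are oriented so every exposure effect is non-negative (both signs
    flipped otherwise).  Weights are 1/se_out^2; the residual variance is
    floored at 1 so the multiplicative random-effects SE never undercuts the
    fixed-effects SE.  P-values use the t distribution with n_snp - 2 df.
    """
    if len(h) < 3:
        raise InsufficientSnpsError("MR-Egger needs at least 3 SNPs")
    bx, _, by, so = _arrays(h)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / so**2
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    # statsmodels scales by the estimated residual variance; floor it at 1
    scale = float(fit.scale)
    infl = np.sqrt(max(1.0, scale) / scale)
    se_int, se_slope = fit.bse * infl
    a, b = fit.params
    df = len(h) - 2
    p_slope = float(2 * stats.t.sf(abs(b / se_slope), df))
    p_int = float(2 * stats.t.sf(abs(a / se_int), df))
    slope = MREstimate("egger", float(b), float(se_slope), p_slope, len(h))
    intercept = PleiotropyTest(float(a), float(se_int), p_int)
    return slope, intercept


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    The point estimate is the inverse-variance weighted median of the Wald
    ratios, linearly interpolated in cumulative weight; the SE comes from
    ``n_boot`` parametric resamples of (beta_exp, beta_out) from normals with
    their reported standard errors.
    """
    if len(h) < 3:
        raise InsufficientSnpsError("weighted median needs at least 3 SNPs")
    bx, sx, by, so = _arrays(h)
    beta = _weighted_median_point(bx, by, so)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, so)
        boots[i] = _weighted_median_point(bxs, bys, so)
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", beta, se,
                      _two_sided_normal_p(beta / se), len(h))


def _weighted_median_point(bx, by, so) -> float:
    ratios = by / bx
    w = (np.abs(bx) / so) ** 2
    order = np.argsort(ratios)
    r = ratios[order]
    w = w[order] / w.sum()
    # cumulative weight at each ratio, centred on its own weight
    cum = np.cumsum(w) - w / 2
    if 0.5 <= cum[0]:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(cum, 0.5) - 1)
    frac = (0.5 - cum[k]) / (cum[k + 1] - cum[k])
    return float(r[k] + frac * (r[k + 1] - r[k]))


def beta_to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Convert a log-odds effect to an odds ratio with a 95% Wald CI."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (float(np.exp(beta)),
            float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)))
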