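"""Two-step mediation Mendelian randomization.

Step 1 estimates the effect of the exposure on each candidate mediator
(beta1); step 2 estimates each mediator's effect on the outcome (beta2).  A
trait qualifies as a mediator when both steps survive family-wise BH/FDR
control and neither step's Egger intercept flags directional pleiotropy.
The mediated (indirect) effect is the product of coefficients beta1*beta2,
reported as a signed percentage of the total exposure-outcome effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyInputError,
    EmptyOverlapError,
    UndefinedProportionError,
)
from .mr_core import MREstimate, egger, ivw
from .multiplicity import QValueSet, family_filter
from .summary_data import (
    AnalysisConfig,
    GwasTable,
    HarmonizedSet,
    LdMatrix,
    exclude_outcome_associated,
    harmonize,
    select_instruments,
)

logger = logging.getLogger(__name__)


def mediation_effect(beta1: float, beta2: float) -> float:
    """Indirect effect by the product of coefficients: beta1 * beta2."""
    return beta1 * beta2


def mediation_proportion(mediation_effect: float, total_effect: float) -> float:
    """Mediated effect as a signed percentage of the total effect.

    Negative proportions (mediator pulling against the total effect) and
    proportions above 100% pass through unchanged.
    """
    if total_effect == 0:
        raise UndefinedProportionError("total effect is zero")
    return 100.0 * mediation_effect / total_effect


def sobel_se(beta1: float, se1: float, beta2: float, se2: float) -> float:
    """First-order delta-method SE of the product beta1*beta2 (Sobel)."""
    return float(np.sqrt(beta2**2 * se1**2 + beta1**2 * se2**2))


@dataclass
class MediationResult:
    """One mediator's two-step estimates and its share of the total effect."""

    mediator_id: str
    mediator_label: str
    beta1: float
    se1: float
    pval1: float
    qval1: float
    n_snp1: int
    egger_intercept1: float
    egger_pval1: float
    beta2: float
    se2: float
    pval2: float
    qval2: float
    n_snp2: int
    egger_intercept2: float
    egger_pval2: float
    total_effect: float
    pleiotropy_ok: bool

    @property
    def mediation_effect(self) -> float:
        return mediation_effect(self.beta1, self.beta2)

    @property
    def sobel_se(self) -> float:
        return sobel_se(self.beta1, self.se1, self.beta2, self.se2)

    @property
    def proportion_pct(self) -> float:
        return mediation_proportion(self.mediation_effect, self.total_effect)


def results_to_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "mediator_id": r.mediator_id, "mediator_label": r.mediator_label,
            "n_snp1": r.n_snp1, "beta1": r.beta1, "se1": r.se1,
            "pval1": r.pval1, "qval1": r.qval1,
            "egger_int1": r.egger_intercept1, "egger_p1": r.egger_pval1,
            "n_snp2": r.n_snp2, "beta2": r.beta2, "se2": r.se2,
            "pval2": r.pval2, "qval2": r.qval2,
            "egger_int2": r.egger_intercept2, "egger_p2": r.egger_pval2,
            "mediation_effect": r.mediation_effect, "sobel_se": r.sobel_se,
            "total_effect": r.total_effect, "proportion_pct": r.proportion_pct,
        })
    cols = ["mediator_id", "mediator_label", "n_snp1", "beta1", "se1", "pval1",
            "qval1", "egger_int1", "egger_p1", "n_snp2", "beta2", "se2",
            "pval2", "qval2", "egger_int2", "egger_p2", "mediation_effect",
            "sobel_se", "total_effect", "proportion_pct"]
    return pd.DataFrame(rows, columns=cols)


def _mr_step(h: HarmonizedSet, config: AnalysisConfig):
    """IVW estimate plus Egger intercept screen for one harmonized set."""
    est, het = ivw(h, config)
    if len(h) >= 3:
        _, intercept = egger(h)
        egger_int, egger_p = intercept.intercept, intercept.pval
        flagged = egger_p < config.pleiotropy_alpha
    else:  # too few SNPs to fit an intercept; cannot flag pleiotropy
        egger_int, egger_p, flagged = np.nan, np.nan, False
    return est, het, egger_int, egger_p, flagged


def two_step_mediation(
    exposure: GwasTable,
    mediators,
    outcome: GwasTable,
    config: AnalysisConfig | None = None,
    ld: LdMatrix | None = None,
    include_nonsignificant: bool = False,
):
    """Run the full two-step mediation MR analysis.

    Step 0 estimates the total exposure->outcome effect from the exposure's
    instruments (outcome-associated instruments excluded).  Step 1 estimates
    exposure->mediator for every candidate, step 2 mediator->outcome from
    each mediator's own instruments; each step is BH-adjusted across the
    candidate family.  A mediator is reported when both q-values fall below
    ``fdr_alpha`` and neither step's Egger intercept flags pleiotropy at
    ``pleiotropy_alpha``.  Set ``include_nonsignificant`` to also return the
    non-qualifying candidates (flagged by ``pleiotropy_ok``/q-values).

    Returns ``(results, total_effect_estimate, details)`` where ``details``
    maps step names to their :class:`~mrmediate.multiplicity.QValueSet`.
    """
    config = config or AnalysisConfig()

    instr_exp = select_instruments(exposure, config, ld)
    if len(instr_exp) == 0:
        raise EmptyInputError("no instruments for the exposure")
    h_total = exclude_outcome_associated(
        harmonize(instr_exp, outcome, config.palindrome_eaf_band),
        p_threshold=config.outcome_exclusion_p)
    total_est, _ = ivw(h_total, config)
    if outcome.is_binary:
        total_est = total_est.with_or()

    step1: dict[str, tuple] = {}
    step2: dict[str, tuple] = {}
    labels: dict[str, str] = {}
    for med in mediators:
        labels[med.trait_id] = med.trait_label
        try:
            h1 = harmonize(instr_exp, med, config.palindrome_eaf_band)
            step1[med.trait_id] = _mr_step(h1, config)
        except (EmptyOverlapError, EmptyInputError) as exc:
            logger.warning("mediator %s skipped in step 1: %s", med.trait_id, exc)
            continue
        try:
            instr_med = select_instruments(med, config, ld)
            if len(instr_med) == 0:
                raise EmptyInputError("no instruments")
            h2 = exclude_outcome_associated(
                harmonize(instr_med, outcome, config.palindrome_eaf_band),
                p_threshold=config.outcome_exclusion_p)
            step2[med.trait_id] = _mr_step(h2, config)
        except (EmptyOverlapError, EmptyInputError) as exc:
            logger.warning("mediator %s skipped in step 2: %s", med.trait_id, exc)
            del step1[med.trait_id]

    if not step1:
        return [], total_est, {"step1": None, "step2": None}

    ids = list(step1)
    q1 = family_filter({i: step1[i][0].pval for i in ids}, config.fdr_alpha)
    q2 = family_filter({i: step2[i][0].pval for i in ids}, config.fdr_alpha)
    q1_map = dict(zip(q1.ids, q1.qvals))
    q2_map = dict(zip(q2.ids, q2.qvals))

    results = []
    for mid in ids:
        est1, _, int1, p_int1, flag1 = step1[mid]
        est2, _, int2, p_int2, flag2 = step2[mid]
        pleio_ok = not (flag1 or flag2)
        qualifies = (q1_map[mid] < config.fdr_alpha
                     and q2_map[mid] < config.fdr_alpha and pleio_ok)
        if not (qualifies or include_nonsignificant):
            continue
        results.append(MediationResult(
            mediator_id=mid, mediator_label=labels[mid],
            beta1=est1.beta, se1=est1.se, pval1=est1.pval,
            qval1=float(q1_map[mid]), n_snp1=est1.n_snp,
            egger_intercept1=int1, egger_pval1=p_int1,
            beta2=est2.beta, se2=est2.se, pval2=est2.pval,
            qval2=float(q2_map[mid]), n_snp2=est2.n_snp,
            egger_intercept2=int2, egger_pval2=p_int2,
            total_effect=total_est.beta, pleiotropy_ok=pleio_ok,
        ))
    return results, total_est, {"step1": q1, "step2": q2}


@dataclass
class SourceComparison:
    """Sign agreement of per-source effect estimates for shared traits."""

    trait_ids: list
    betas: pd.DataFrame  # index trait_id, one column per source
    consistent: dict  # trait_id -> bool


def cross_source_consistency(per_source: dict, alpha: float = 0.05
                             ) -> SourceComparison:
    """Compare effect directions across data sources.

    ``per_source`` maps a source label to a DataFrame with columns
    ``trait_id``, ``beta``, ``qval``.  Traits significant (qval < alpha) in
    every source are retained; a trait is consistent when all pairwise
    products of its per-source betas are positive, i.e. the sign is
    unanimous.
    """
    if len(per_source) < 2:
        raise ConfigurationError("cross-source comparison needs >= 2 sources")
    sig_sets = []
    beta_maps = {}
    for src, df in per_source.items():
        sig_sets.append(set(df.loc[df["qval"] < alpha, "trait_id"]))
        beta_maps[src] = df.set_index("trait_id")["beta"]
    shared = sorted(set.intersection(*sig_sets))
    betas = pd.DataFrame({src: beta_maps[src].reindex(shared)
                          for src in per_source})
    consistent = {
        t: bool((betas.loc[t] > 0).all() or (betas.loc[t] < 0).all())
        for t in shared
    }
    return SourceComparison(trait_ids=shared, betas=betas, consistent=consistent)
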