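"""Synthetic GWAS summary statistics with known causal structure.

Generates three linked traits — exposure, mediator(s), binary outcome — the
way a two-sample MR study consumes them: per-SNP instrument effects on the
exposure, mediator effects proportional to them (theta1), and outcome
effects combining the direct path (tau_direct) and the mediated paths
(sum of theta1*theta2), optionally contaminated with balanced or directional
horizontal pleiotropy.  Every generated table satisfies the GwasTable
invariants and the generating truth is returned alongside for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .summary_data import GwasTable

_NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for a three-trait summary-statistics system.

    Defaults describe a well-powered desk-scale study: 30 independent strong
    exposure instruments (half-normal per-SNP effects with scale 0.15,
    oriented so the effect allele increases the exposure, against an exposure
    SE of 0.003 — essentially all instruments reach genome-wide significance),
    one mediator with exposure->mediator effect 0.2 and mediator->outcome
    effect 0.3, a direct exposure->outcome effect of 0.3 (total effect 0.36,
    true proportion mediated 16.7%), and no pleiotropy.

    Each mediator additionally receives ``n_snp_mediator`` instruments of its
    own — SNPs with direct effects on the mediator (SD ``gamma_sd``) and on
    the outcome only through the mediator (times theta2).  Without them the
    mediator->outcome step would have no valid instruments: SNPs acting on
    the mediator solely through the exposure violate the exclusion
    restriction for that step, since the exposure's direct path to the
    outcome is open.
    """

    n_snp: int = 30
    n_snp_mediator: int = 30
    n_mediators: int = 1
    gamma_sd: float = 0.15
    theta1: tuple = (0.2,)
    theta2: tuple = (0.3,)
    tau_direct: float = 0.3
    se_exp: float = 0.003
    se_med: float = 0.02
    se_out: float = 0.03
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.02
    maf_range: tuple = (0.05, 0.40)
    n_exp: int = 322_154
    n_med: int = 115_078
    n_out: int = 401_832
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 4:
            raise ConfigurationError("n_snp must be at least 4")
        if self.n_mediators > 0 and self.n_snp_mediator < 4:
            raise ConfigurationError("n_snp_mediator must be at least 4")
        if len(self.theta1) != self.n_mediators or len(self.theta2) != self.n_mediators:
            raise ConfigurationError("theta1/theta2 lengths must equal n_mediators")
        for name in ("gamma_sd", "se_exp", "se_med", "se_out"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ConfigurationError("maf_range must be a sub-interval of (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode != "none" and self.pleiotropy_sd <= 0:
            raise ConfigurationError("pleiotropy_sd must be positive")

    @property
    def total_effect(self) -> float:
        return self.tau_direct + float(
            np.dot(np.asarray(self.theta1), np.asarray(self.theta2)))


@dataclass
class SimulationTruth:
    """Realized generating quantities of one simulated dataset."""

    gamma: np.ndarray  # exposure-instrument effects on the exposure
    delta: np.ndarray  # (n_mediators, n_snp_mediator) mediator-own effects
    alpha_outcome: np.ndarray  # per-SNP direct (pleiotropic) outcome effects
    alpha_mediators: np.ndarray  # (n_mediators, n_snp) pleiotropic effects
    theta1: tuple
    theta2: tuple
    tau_direct: float
    total_effect: float
    proportion_pct: np.ndarray = field(default=None)  # per mediator

    def __post_init__(self) -> None:
        t1 = np.asarray(self.theta1, dtype=float)
        t2 = np.asarray(self.theta2, dtype=float)
        self.proportion_pct = 100.0 * t1 * t2 / self.total_effect


def _snp_frame(rng, cfg: SimulationConfig, n: int) -> pd.DataFrame:
    # one SNP per 20 Mb, cycling chromosomes, so default clumping windows
    # never overlap
    chroms = [str(1 + i % 22) for i in range(n)]
    pos = [1_000_000 + 20_000_000 * (i // 22) for i in range(n)]
    pairs = [_NON_PALINDROMIC_PAIRS[i] for i in
             rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=n)]
    eaf = rng.uniform(*cfg.maf_range, size=n)
    return pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(n)],
        "chr": chroms,
        "pos": pos,
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "eaf": eaf,
    })


def _finish_table(base: pd.DataFrame, beta, se_scale: float, n: int,
                  trait_id: str, label: str, kind: str) -> GwasTable:
    df = base.copy()
    df["beta"] = beta
    df["se"] = se_scale
    df["pval"] = 2 * stats.norm.sf(np.abs(beta) / se_scale)
    df["pval"] = df["pval"].clip(lower=np.nextafter(0, 1), upper=1.0)
    df["n"] = float(n)
    return GwasTable(trait_id=trait_id, trait_label=label, trait_kind=kind,
                     records=df, provenance={"synthetic": True})


def simulate_three_trait_gwas(config: SimulationConfig
                              ) -> tuple[GwasTable, list, GwasTable, SimulationTruth]:
    """Generate (exposure, mediators, outcome, truth) summary tables.

    The SNP panel has one block of ``n_snp`` exposure instruments (true
    effects gamma_j ~ N(0, gamma_sd²) on the exposure) and, per mediator, a
    block of ``n_snp_mediator`` mediator-own instruments (effects delta ~
    N(0, gamma_sd²) on that mediator, null on the exposure).  True effects
    flow along the causal graph: mediator m sees theta1_m * gamma on the
    exposure block plus delta on its own block; the outcome sees
    (tau_direct + sum theta1*theta2) * gamma on the exposure block and
    theta2_m * delta on mediator blocks.  Optional per-SNP pleiotropic
    effects alpha (balanced: mean zero; directional: mean
    ``pleiotropy_mean``) contaminate the exposure block.  Observed betas add
    N(0, se²) study noise; every table reports the same homoscedastic SE
    column and shares SNP identity and allele coding, mirroring harmonized
    multi-study summary data.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snp
    nm = config.n_snp_mediator
    n_total = n + config.n_mediators * nm
    base = _snp_frame(rng, config, n_total)
    exp_block = slice(0, n)

    def med_block(m):
        return slice(n + m * nm, n + (m + 1) * nm)

    # effect alleles are oriented to the trait-increasing direction, as
    # instrument lists conventionally report them; directional pleiotropy is
    # only meaningful relative to such a fixed orientation
    gamma = np.abs(rng.normal(0.0, config.gamma_sd, size=n))
    delta = np.abs(rng.normal(0.0, config.gamma_sd, size=(config.n_mediators, nm)))

    def pleio(size):
        if config.pleiotropy_mode == "none":
            return np.zeros(size)
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        return rng.normal(mean, config.pleiotropy_sd, size=size)

    true_exp = np.zeros(n_total)
    true_exp[exp_block] = gamma
    beta_exp = true_exp + rng.normal(0.0, config.se_exp, size=n_total)
    exposure = _finish_table(base, beta_exp, config.se_exp, config.n_exp,
                             "sim-exposure", "simulated exposure", "continuous")

    alpha_med = np.zeros((config.n_mediators, n))
    mediators = []
    for m in range(config.n_mediators):
        alpha_med[m] = pleio(n)
        true_m = np.zeros(n_total)
        true_m[exp_block] = config.theta1[m] * gamma + alpha_med[m]
        true_m[med_block(m)] = delta[m]
        beta_m = true_m + rng.normal(0.0, config.se_med, size=n_total)
        mediators.append(_finish_table(
            base, beta_m, config.se_med, config.n_med,
            f"sim-mediator-{m + 1}", f"simulated mediator {m + 1}", "continuous"))

    alpha_out = pleio(n)
    true_out = np.zeros(n_total)
    true_out[exp_block] = config.total_effect * gamma + alpha_out
    for m in range(config.n_mediators):
        true_out[med_block(m)] = config.theta2[m] * delta[m]
    beta_out = true_out + rng.normal(0.0, config.se_out, size=n_total)
    outcome = _finish_table(base, beta_out, config.se_out, config.n_out,
                            "sim-outcome", "simulated outcome", "binary")

    truth = SimulationTruth(
        gamma=gamma, delta=delta, alpha_outcome=alpha_out,
        alpha_mediators=alpha_med,
        theta1=config.theta1, theta2=config.theta2,
        tau_direct=config.tau_direct, total_effect=config.total_effect,
    )
    return exposure, mediators, outcome, truth


def simulate_null_family(m: int, config: SimulationConfig | None = None,
                         seed: int | None = None) -> np.ndarray:
    """IVW p-values for ``m`` independent exposure->trait tests with no effect.

    Each family member draws its own instrument effects and noise; the
    outcome trait carries no causal signal, so the returned p-values are
    uniform under correct calibration.  Fixed-effect IVW is used throughout
    (there is no heterogeneity under this null).
    """
    if m < 1:
        raise ConfigurationError("m must be at least 1")
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_snp
    gamma = rng.normal(0.0, config.gamma_sd, size=(m, n))
    bx = gamma + rng.normal(0.0, config.se_exp, size=(m, n))
    by = rng.normal(0.0, config.se_out, size=(m, n))  # no causal path
    w = 1.0 / config.se_out**2
    beta = np.sum(w * bx * by, axis=1) / np.sum(w * bx**2, axis=1)
    se = np.sum(w * bx**2, axis=1) ** -0.5
    return 2 * stats.norm.sf(np.abs(beta / se))
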