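"""Orchestration of the four-step mediation-MR workflow, plus packaged
reference fixtures.

The packaged fixtures are machine-readable copies of a published two-sample
MR screen: the exposure->metabolite table (176 body-mass-index-associated
NMR metabolic traits), the metabolite->gallstone-disease table (85 traits),
and the 49-row mediator table combining both steps.  ``verify_fixtures``
recomputes every derivable cell (odds ratios and confidence limits from beta
and SE, Egger intercept p-values from intercept, SE and SNP count, mediation
effects as products of coefficients, and the mediator-set intersection) and
reports any cell that cannot be explained by last-digit rounding of the
printed three-significant-figure values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .mediation import results_to_frame, two_step_mediation
from .summary_data import AnalysisConfig, GwasTable, LdMatrix

logger = logging.getLogger(__name__)

_FIXTURES = {
    "exposure_to_mediators": "bmi_to_metabolites.tsv",
    "mediators_to_outcome": "metabolites_to_cholelithiasis.tsv",
    "mediators": "mediators.tsv",
}


def load_fixtures() -> dict:
    """Load the packaged reference-screen tables as DataFrames."""
    root = resources.files("mrmediate") / "fixtures"
    return {k: pd.read_csv(str(root / v), sep="\t") for k, v in _FIXTURES.items()}


# ---------------------------------------------------------------------------
# fixture verification

def _half_unit(v: float) -> float:
    """Half of one unit in the last digit of a 3-significant-figure value."""
    if v == 0:
        return 5e-4
    return 0.5 * 10.0 ** (np.floor(np.log10(abs(v))) - 2)


def _interval_or(beta: float, se: float, z: float) -> tuple[float, float]:
    hb, hs = _half_unit(beta), _half_unit(se)
    corners = [np.exp((beta + s1 * hb) + z * (se + s2 * hs))
               for s1 in (-1, 1) for s2 in (-1, 1)]
    return min(corners), max(corners)


def _interval_product(a: float, b: float) -> tuple[float, float]:
    ha, hb = _half_unit(a), _half_unit(b)
    corners = [(a + s1 * ha) * (b + s2 * hb)
               for s1 in (-1, 1) for s2 in (-1, 1)]
    return min(corners), max(corners)


def _interval_egger_p(intercept: float, se: float, df: int) -> tuple[float, float]:
    hi_, hs = _half_unit(intercept), _half_unit(se)
    t_min = max(0.0, abs(intercept) - hi_) / (se + hs)
    t_max = (abs(intercept) + hi_) / max(se - hs, 1e-300)
    return (float(2 * stats.t.sf(t_max, df)), float(2 * stats.t.sf(t_min, df)))


def _check_cell(rows, table, trait_id, cell, printed, lo, hi, recomputed):
    ok = (printed + _half_unit(printed) >= lo) and (printed - _half_unit(printed) <= hi)
    rows.append({"table": table, "trait_id": trait_id, "cell": cell,
                 "printed": printed, "recomputed": recomputed, "ok": ok})


def verify_fixtures(fixtures: dict | None = None) -> pd.DataFrame:
    """Recompute every derivable fixture cell; return a discrepancy report.

    Each row of the report carries the printed value, the value recomputed
    from the row's other columns, and an ``ok`` flag that is False only when
    the printed value cannot be explained by rounding of the printed inputs
    to three significant figures.
    """
    fx = fixtures or load_fixtures()
    rows: list[dict] = []

    d3 = fx["mediators_to_outcome"]
    for _, r in d3.iterrows():
        for col, z in (("or_", 0.0), ("lci95", -1.96), ("uci95", 1.96)):
            lo, hi = _interval_or(r["beta"], r["se"], z)
            _check_cell(rows, "mediators_to_outcome", r["trait_id"], col,
                        r[col], lo, hi, float(np.exp(r["beta"] + z * r["se"])))

    for table in ("exposure_to_mediators", "mediators_to_outcome"):
        for _, r in fx[table].iterrows():
            df_ = int(r["n_snp"]) - 2
            lo, hi = _interval_egger_p(r["egger_intercept"], r["egger_se"], df_)
            recomputed = float(
                2 * stats.t.sf(abs(r["egger_intercept"] / r["egger_se"]), df_))
            _check_cell(rows, table, r["trait_id"], "egger_pval",
                        r["egger_pval"], lo, hi, recomputed)

    d4 = fx["mediators"]
    for _, r in d4.iterrows():
        for step in ("1", "2"):
            df_ = int(r[f"n_snp{step}"]) - 2
            lo, hi = _interval_egger_p(
                r[f"egger_intercept{step}"], r[f"egger_se{step}"], df_)
            recomputed = float(2 * stats.t.sf(
                abs(r[f"egger_intercept{step}"] / r[f"egger_se{step}"]), df_))
            _check_cell(rows, "mediators", r["trait_id"], f"egger_pval{step}",
                        r[f"egger_pval{step}"], lo, hi, recomputed)
        lo, hi = _interval_product(r["beta1"], r["beta2"])
        _check_cell(rows, "mediators", r["trait_id"], "mediation_effect",
                    r["mediation_effect"], lo, hi,
                    float(r["beta1"] * r["beta2"]))

    # mediator set: every mediator row must appear in both screens, and the
    # intersection of the two screens must be exactly the mediator set
    inter = set(fx["exposure_to_mediators"]["trait_id"]) & set(d3["trait_id"])
    med_ids = set(d4["trait_id"])
    rows.append({"table": "mediators", "trait_id": "(all)",
                 "cell": "intersection_count", "printed": float(len(med_ids)),
                 "recomputed": float(len(inter)), "ok": inter == med_ids})
    report = pd.DataFrame(rows)
    n_bad = int((~report["ok"]).sum())
    logger.info("verify_fixtures: %d cells checked, %d discrepancies",
                len(report), n_bad)
    return report


# ---------------------------------------------------------------------------
# full analysis

@dataclass
class RunManifest:
    """Provenance of one full analysis run."""

    config_hash: str
    software_version: str
    inputs: dict  # table id -> row count
    stages: list = field(default_factory=list)

    def add_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str, **kwargs)


def run_full_analysis(
    exposure: GwasTable,
    mediators,
    outcome: GwasTable,
    config: AnalysisConfig | None = None,
    ld: LdMatrix | None = None,
):
    """Run the four-step workflow and return (results, total effect, manifest).

    Steps: (1) total exposure->outcome effect; (2) exposure->mediator screen
    with FDR and Egger-intercept gatekeeping; (3) mediator->outcome screen,
    same gatekeeping plus exclusion of outcome-associated instruments;
    (4) mediation synthesis (product of coefficients, proportion of total).
    """
    config = config or AnalysisConfig()
    mediators = list(mediators)
    if exposure.trait_id.split("/")[-1] == outcome.trait_id.split("/")[-1]:
        logger.warning("exposure and outcome share a source label; "
                       "two-sample assumptions may be violated")
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]
    manifest = RunManifest(
        config_hash=cfg_hash,
        software_version=__version__,
        inputs={t.trait_id: len(t) for t in [exposure, outcome, *mediators]},
    )

    results, total_est, details = two_step_mediation(
        exposure, mediators, outcome, config, ld)

    manifest.add_stage("total_effect", exposure=exposure.trait_id,
                       outcome=outcome.trait_id, n_snp=total_est.n_snp,
                       beta=total_est.beta, se=total_est.se,
                       method=total_est.method)
    for step in ("step1", "step2"):
        q = details[step]
        manifest.add_stage(step,
                           n_tested=0 if q is None else len(q.ids),
                           n_significant=0 if q is None else int(q.significant.sum()))
    manifest.add_stage("mediation", n_mediators=len(results),
                       mediator_ids=[r.mediator_id for r in results])
    return results, total_est, manifest


def write_outputs(results, total_est, manifest, out_dir) -> None:
    """Write the mediation TSV and manifest JSON to ``out_dir``."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = results_to_frame(results)
    frame.to_csv(out / "mediation_results.tsv", sep="\t", index=False,
                 float_format="%.12g")
    (out / "manifest.json").write_text(manifest.to_json(indent=2) + "\n")
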