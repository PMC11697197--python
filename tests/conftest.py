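import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrmediate import GwasTable, HarmonizedSet, SimulationConfig, simulate_three_trait_gwas

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

logging.getLogger("mrmediate").setLevel(logging.ERROR)

_NT_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]


def random_gwas_frame(rng: np.random.Generator, n: int = 20,
                      missing_eaf: bool = False) -> pd.DataFrame:
    """A valid random summary-statistics frame for round-trip/oracle tests."""
    pairs = [_NT_PAIRS[i] for i in rng.integers(0, len(_NT_PAIRS), n)]
    eaf = rng.uniform(0.05, 0.95, n)
    if missing_eaf:
        eaf[rng.random(n) < 0.3] = np.nan
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(n)],
        "chr": rng.integers(1, 23, n).astype(str),
        "pos": rng.integers(1, 2_000_000, n),
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "eaf": eaf,
        "beta": rng.normal(0, 0.2, n),
        "se": rng.uniform(0.01, 0.1, n),
        "pval": rng.uniform(1e-12, 1, n),
        "n": np.full(n, 10_000.0),
    })


def make_table(frame: pd.DataFrame, trait_id: str = "trait",
               kind: str = "continuous") -> GwasTable:
    return GwasTable(trait_id=trait_id, trait_label=trait_id,
                     trait_kind=kind, records=frame.reset_index(drop=True))


def make_harmonized(rng: np.random.Generator, n: int = 20,
                    beta: float = 0.3, het_sd: float = 0.0) -> HarmonizedSet:
    """Harmonized pairs generated directly, around a true slope ``beta``."""
    bx = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    sx = rng.uniform(0.002, 0.01, n)
    so = rng.uniform(0.02, 0.08, n)
    by = beta * bx + rng.normal(0, het_sd, n) + rng.normal(0, so)
    return HarmonizedSet(
        exposure_id="x", outcome_id="y",
        pairs=pd.DataFrame({
            "snp": [f"rs{i}" for i in range(n)],
            "beta_exp": bx, "se_exp": sx, "pval_exp": np.full(n, 1e-9),
            "beta_out": by, "se_out": so, "pval_out": np.full(n, 0.5),
            "eaf_exp": np.full(n, 0.3), "eaf_out": np.full(n, 0.3),
        }))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def one_mediator_system():
    """Default simulated three-trait system with one true mediator."""
    return simulate_three_trait_gwas(SimulationConfig(seed=42))
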