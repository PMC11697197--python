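"""Benjamini-Hochberg false-discovery-rate control over families of MR tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError


@dataclass
class QValueSet:
    """BH-adjusted q-values for one family of tests."""

    ids: list
    pvals: np.ndarray
    qvals: np.ndarray
    alpha: float
    significant: np.ndarray  # boolean, qval < alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "pval": self.pvals,
            "qval": self.qvals, "significant": self.significant,
        })


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    For p sorted ascending, q(i) = min_{j >= i} m * p(j) / j, mapped back to
    the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def family_filter(pvals_by_id: dict, alpha: float = 0.05) -> QValueSet:
    """BH-adjust one family of per-trait p-values and mark significance.

    ``pvals_by_id`` maps a trait identifier to its raw p-value (one test per
    trait, a single family — e.g. one exposure screened against each of the
    249 metabolic traits).  A sequence of ``(id, pval)`` pairs is also
    accepted; duplicate ids are rejected.
    """
    items = (list(pvals_by_id.items())
             if isinstance(pvals_by_id, dict) else list(pvals_by_id))
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate trait keys in family")
    p = np.array([v for _, v in items], dtype=float)
    q = bh_adjust(p)
    return QValueSet(ids=ids, pvals=p, qvals=q, alpha=alpha,
                     significant=q < alpha)
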