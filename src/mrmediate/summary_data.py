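"""GWAS summary statistics: data model, I/O, instrument selection, harmonization.

A :class:`GwasTable` holds one trait's per-SNP association summaries (effect
size ``beta`` on the trait scale — log-odds for binary traits — with standard
error, p-value, allele coding and effect-allele frequency).  Instrument
selection applies the usual genome-wide significance threshold followed by
greedy LD clumping; harmonization aligns an exposure and an outcome table to a
common effect allele so that every downstream estimator sees consistent
(beta_exp, beta_out) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    ColumnMappingError,
    ConfigurationError,
    EmptyInputError,
    EmptyOverlapError,
    SnpNotInLdError,
)

logger = logging.getLogger(__name__)

#: canonical column order of the on-disk dialect
STANDARD_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and sizes governing a full two-sample MR analysis.

    Defaults implement the conventional instrument-selection criteria:
    genome-wide significance p < 5e-8, LD clumping at r² < 0.001 within a
    10,000 kb window, and exclusion of instruments associated with the
    outcome at genome-wide significance.
    """

    instrument_p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    outcome_exclusion_p: float = 5e-8
    q_test_alpha: float = 0.05
    fdr_alpha: float = 0.05
    pleiotropy_alpha: float = 0.05
    palindrome_eaf_band: float = 0.08
    median_bootstrap_n: int = 1000
    presso_sim_n: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("instrument_p_threshold", "clump_r2", "outcome_exclusion_p",
                     "q_test_alpha", "fdr_alpha", "pleiotropy_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        if self.clump_window_kb <= 0:
            raise ConfigurationError("clump_window_kb must be positive")
        if self.median_bootstrap_n <= 0 or self.presso_sim_n <= 0:
            raise ConfigurationError("bootstrap/simulation counts must be positive")


@dataclass
class GwasTable:
    """Per-trait summary statistics, one row per SNP, unique by ``snp``."""

    trait_id: str
    trait_label: str
    trait_kind: str  # "continuous" or "binary"
    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_kind not in ("continuous", "binary"):
            raise ConfigurationError(
                f"trait_kind must be 'continuous' or 'binary', got {self.trait_kind!r}")
        missing = [c for c in STANDARD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ColumnMappingError(f"records missing columns: {missing}")
        if self.records["snp"].duplicated().any():
            raise ConfigurationError("duplicate snp identifiers in records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def is_binary(self) -> bool:
        return self.trait_kind == "binary"


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop rows violating record invariants; return (clean frame, drop counts)."""
    counts = {}
    ok = df["se"].notna() & (df["se"] > 0)
    counts["dropped_se_nonpositive"] = int((~ok).sum())
    df = df[ok]

    ok = df["pval"].notna() & (df["pval"] > 0) & (df["pval"] <= 1)
    counts["dropped_pval_invalid"] = int((~ok).sum())
    df = df[ok]

    ok = df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))
    counts["dropped_eaf_invalid"] = int((~ok).sum())
    df = df[ok]

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    ok = ea.isin(_COMPLEMENT) & oa.isin(_COMPLEMENT) & (ea != oa)
    counts["dropped_allele_invalid"] = int((~ok).sum())
    df = df.assign(effect_allele=ea, other_allele=oa)[ok]

    # duplicate snp ids: keep the smallest p-value (ties: first occurrence)
    df = df.sort_values("pval", kind="stable")
    dup = df["snp"].duplicated()
    counts["dropped_duplicate_snp"] = int(dup.sum())
    df = df[~dup].sort_index()
    return df.reset_index(drop=True), counts


def read_gwas_table(
    path,
    column_map: dict | None = None,
    trait_kind: str = "continuous",
    trait_id: str | None = None,
    trait_label: str | None = None,
    sep: str = "\t",
) -> GwasTable:
    """Read a delimited summary-statistics file into a validated GwasTable.

    ``column_map`` maps standard field names (``snp``, ``chr``, ``pos``,
    ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``,
    ``n``) to the file's actual headers; omit it when the file already uses
    the standard names.  Rows violating record invariants are dropped and
    counted in ``provenance``.
    """
    raw = pd.read_csv(path, sep=sep, na_values=["NA"], dtype={0: str})
    column_map = column_map or {}
    rename = {}
    for std in STANDARD_COLUMNS:
        src = column_map.get(std, std)
        if src not in raw.columns:
            if std in ("eaf", "n", "chr", "pos"):
                raw[std] = np.nan if std in ("eaf", "n") else ("0" if std == "chr" else 0)
                continue
            raise ColumnMappingError(
                f"column {src!r} (standard field {std!r}) not found in {path}")
        rename[src] = std
    df = raw.rename(columns=rename)[STANDARD_COLUMNS].copy()
    df["snp"] = df["snp"].astype(str)
    df["chr"] = df["chr"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").fillna(0).astype(np.int64)
    for c in ("eaf", "beta", "se", "pval", "n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")

    clean, counts = _validate_rows(df)
    if len(clean) == 0:
        raise EmptyInputError(f"no valid rows in {path}")
    for k, v in counts.items():
        if v:
            logger.info("read_gwas_table(%s): %s = %d", path, k, v)
    name = str(path)
    return GwasTable(
        trait_id=trait_id or name,
        trait_label=trait_label or trait_id or name,
        trait_kind=trait_kind,
        records=clean,
        provenance={"path": name, **counts},
    )


def write_gwas_table(table: GwasTable, path) -> None:
    """Write a GwasTable to tab-separated text; lossless to 12 significant digits.

    Missing ``eaf``/``n`` values are written as the explicit marker ``NA``.
    """
    out = table.records[STANDARD_COLUMNS].copy()
    for c in ("eaf", "beta", "se", "pval", "n"):
        out[c] = out[c].map(lambda v: "NA" if pd.isna(v) else f"{v:.12g}")
    out.to_csv(path, sep="\t", index=False)


@dataclass
class LdMatrix:
    """Pairwise squared correlations (r²) between SNPs, with unit diagonal."""

    snp_ids: list
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ConfigurationError("r2 matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ConfigurationError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ConfigurationError("r2 diagonal must be exactly 1")
        if (self.r2 < 0).any() or (self.r2 > 1).any():
            raise ConfigurationError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @classmethod
    def identity(cls, snp_ids) -> "LdMatrix":
        return cls(list(snp_ids), np.eye(len(list(snp_ids))))

    @classmethod
    def from_long_tsv(cls, path) -> "LdMatrix":
        """Read a 3-column long-format TSV (snp_a, snp_b, r2)."""
        df = pd.read_csv(path, sep="\t")
        ids = sorted(set(df["snp_a"]) | set(df["snp_b"]))
        idx = {s: i for i, s in enumerate(ids)}
        m = np.eye(len(ids))
        for a, b, r in zip(df["snp_a"], df["snp_b"], df["r2"]):
            m[idx[a], idx[b]] = r
            m[idx[b], idx[a]] = r
        return cls(ids, m)

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise SnpNotInLdError(f"SNP {exc.args[0]!r} absent from LD matrix") from exc


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a common effect-allele orientation."""

    exposure_id: str
    outcome_id: str
    pairs: pd.DataFrame  # snp, beta_exp, se_exp, beta_out, se_out, eaf_exp, eaf_out, pval_out
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pairs["snp"].duplicated().any():
            raise ConfigurationError("duplicate snp in harmonized pairs")
        if ((self.pairs["se_exp"] <= 0) | (self.pairs["se_out"] <= 0)).any():
            raise ConfigurationError("all standard errors must be positive")

    def __len__(self) -> int:
        return len(self.pairs)

    def drop_snps(self, snp_ids, reason: str) -> "HarmonizedSet":
        keep = ~self.pairs["snp"].isin(set(snp_ids))
        prov = dict(self.provenance)
        prov[reason] = prov.get(reason, 0) + int((~keep).sum())
        return replace(self, pairs=self.pairs[keep].reset_index(drop=True),
                       provenance=prov)


def greedy_clump(
    records: pd.DataFrame,
    ld: LdMatrix,
    r2_threshold: float,
    window_kb: int,
) -> pd.DataFrame:
    """Greedy p-value-ordered LD clumping.

    Repeatedly keep the record with the smallest p-value and discard every
    other record on the same chromosome within ``window_kb`` whose r² with it
    is at least ``r2_threshold``.  Ties in p-value are broken by
    (chr, pos, snp).  Output is sorted by (chr, pos).
    """
    for s in records["snp"]:
        if s not in ld._index:
            raise SnpNotInLdError(f"SNP {s!r} absent from LD matrix")
    df = records.sort_values(
        ["pval", "chr", "pos", "snp"], kind="stable").reset_index(drop=True)
    window_bp = window_kb * 1000
    alive = np.ones(len(df), dtype=bool)
    kept = np.zeros(len(df), dtype=bool)
    chrom = df["chr"].to_numpy()
    pos = df["pos"].to_numpy()
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept[i] = True
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        for j in np.flatnonzero(near):
            if ld.lookup(df.at[i, "snp"], df.at[j, "snp"]) >= r2_threshold:
                alive[j] = False
    return (df[kept]
            .sort_values(["chr", "pos", "snp"], kind="stable")
            .reset_index(drop=True))


def select_instruments(
    exposure: GwasTable,
    config: AnalysisConfig,
    ld: LdMatrix | None = None,
) -> GwasTable:
    """Select instruments: p < threshold, then greedy LD clumping.

    When no LD matrix is supplied the SNPs are treated as independent (all
    significant SNPs retained) and a warning is logged.
    """
    if len(exposure) == 0:
        raise EmptyInputError("exposure table is empty")
    sig = exposure.records[
        exposure.records["pval"] < config.instrument_p_threshold
    ].reset_index(drop=True)
    n_sig = len(sig)
    if ld is None:
        logger.warning(
            "select_instruments(%s): no LD matrix supplied; treating %d "
            "significant SNPs as independent", exposure.trait_id, n_sig)
        clumped = sig.sort_values(["chr", "pos", "snp"], kind="stable").reset_index(drop=True)
    else:
        clumped = greedy_clump(sig, ld, config.clump_r2, config.clump_window_kb)
    prov = {
        **exposure.provenance,
        "n_input": len(exposure),
        "n_significant": n_sig,
        "n_instruments": len(clumped),
    }
    logger.info("select_instruments(%s): %d -> %d significant -> %d clumped",
                exposure.trait_id, len(exposure), n_sig, len(clumped))
    return replace(exposure, records=clumped, provenance=prov)


def harmonize(
    exposure: GwasTable,
    outcome: GwasTable,
    palindrome_eaf_band: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele.

    Rules, applied per shared SNP:

    * identical coding — keep as is;
    * swapped alleles — negate ``beta_out``, complement ``eaf_out``;
    * strand flip (A<->T, C<->G on both alleles) — treated as identical coding;
    * strand flip plus swap — negate and complement;
    * palindromic (A/T or C/G) SNPs — orientation is not decidable from the
      alleles, so they are kept only when both allele frequencies are present,
      both lie outside ``0.5 ± palindrome_eaf_band``, and they agree in
      orientation (same side of 0.5 after the textual alignment above);
      otherwise dropped;
    * anything else — allele mismatch, dropped.
    """
    exp = exposure.records.set_index("snp")
    out = outcome.records.set_index("snp")
    common = exp.index.intersection(out.index)
    if len(common) == 0:
        raise EmptyOverlapError(
            f"no shared SNPs between {exposure.trait_id} and {outcome.trait_id}")

    counts = {"n_common": len(common), "aligned": 0, "sign_flipped": 0,
              "strand_flipped": 0, "palindromic_kept": 0,
              "palindromic_dropped": 0, "allele_mismatch": 0}
    rows = []
    for snp in common:
        e = exp.loc[snp]
        o = out.loc[snp]
        a1, a2 = e["effect_allele"], e["other_allele"]
        b1, b2 = o["effect_allele"], o["other_allele"]
        beta_out, eaf_out = o["beta"], o["eaf"]

        if (b1, b2) == (a1, a2):
            action = "aligned"
        elif (b1, b2) == (a2, a1):
            action = "sign_flipped"
        elif (_complement(b1), _complement(b2)) == (a1, a2):
            action = "strand_flipped"
        elif (_complement(b1), _complement(b2)) == (a2, a1):
            action = "sign_flipped"
            counts["strand_flipped"] += 1
        else:
            counts["allele_mismatch"] += 1
            continue

        if action == "sign_flipped":
            beta_out = -beta_out
            eaf_out = np.nan if pd.isna(eaf_out) else 1.0 - eaf_out

        if _is_palindromic(a1, a2):
            eaf_exp = e["eaf"]
            lo, hi = 0.5 - palindrome_eaf_band, 0.5 + palindrome_eaf_band
            decidable = (
                pd.notna(eaf_exp) and pd.notna(eaf_out)
                and not lo <= eaf_exp <= hi and not lo <= eaf_out <= hi
                and (eaf_exp - 0.5) * (eaf_out - 0.5) > 0
            )
            if not decidable:
                counts["palindromic_dropped"] += 1
                continue
            counts["palindromic_kept"] += 1
        counts[action] += 1

        rows.append({
            "snp": snp,
            "beta_exp": e["beta"], "se_exp": e["se"], "pval_exp": e["pval"],
            "beta_out": beta_out, "se_out": o["se"], "pval_out": o["pval"],
            "eaf_exp": e["eaf"], "eaf_out": eaf_out,
        })

    if not rows:
        raise EmptyOverlapError(
            f"no harmonizable SNPs between {exposure.trait_id} and {outcome.trait_id}")
    pairs = pd.DataFrame(rows)
    for k, v in counts.items():
        logger.info("harmonize(%s, %s): %s = %d",
                    exposure.trait_id, outcome.trait_id, k, v)
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        pairs=pairs,
        provenance=counts,
    )


def exclude_outcome_associated(
    h: HarmonizedSet,
    outcome: GwasTable | None = None,
    p_threshold: float = 5e-8,
) -> HarmonizedSet:
    """Remove instruments associated with the outcome at ``p < p_threshold``.

    Uses the outcome p-values carried in the harmonized pairs; an outcome
    table may be passed to re-derive them instead.
    """
    pvals = h.pairs["pval_out"]
    if outcome is not None:
        lut = outcome.records.set_index("snp")["pval"]
        pvals = h.pairs["snp"].map(lut).fillna(pvals)
    drop = h.pairs.loc[pvals < p_threshold, "snp"]
    return h.drop_snps(drop, "excluded_outcome_associated")
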