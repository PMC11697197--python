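"""Summary-statistics I/O, instrument selection and harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrmediate import (
    AnalysisConfig,
    GwasTable,
    LdMatrix,
    exclude_outcome_associated,
    greedy_clump,
    harmonize,
    read_gwas_table,
    select_instruments,
    write_gwas_table,
)
from mrmediate.errors import (
    ColumnMappingError,
    EmptyInputError,
    EmptyOverlapError,
    SnpNotInLdError,
)

from .conftest import make_table, random_gwas_frame

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


class TestReadWrite:
    def test_round_trip_is_identity(self, rng, tmp_path):
        """Write-then-read preserves every field to 12 significant digits."""
        table = make_table(random_gwas_frame(rng, 100, missing_eaf=True))
        path = tmp_path / "t.tsv"
        write_gwas_table(table, path)
        back = read_gwas_table(path, trait_id="trait")
        pd.testing.assert_frame_equal(
            back.records, table.records, check_dtype=False,
            rtol=1e-11, atol=0)

    def test_missing_eaf_written_as_na(self, rng, tmp_path):
        frame = random_gwas_frame(rng, 5)
        frame.loc[2, "eaf"] = np.nan
        write_gwas_table(make_table(frame), tmp_path / "t.tsv")
        text = (tmp_path / "t.tsv").read_text()
        assert "\tNA\t" in text

    def test_empty_table_writes_header_only(self, rng, tmp_path):
        frame = random_gwas_frame(rng, 1).iloc[:0]
        write_gwas_table(make_table(frame), tmp_path / "t.tsv")
        lines = (tmp_path / "t.tsv").read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("snp\t")

    def test_invalid_rows_dropped_and_counted(self, rng, tmp_path):
        frame = random_gwas_frame(rng, 5)
        frame.loc[1, "se"] = 0.0
        frame.to_csv(tmp_path / "t.tsv", sep="\t", index=False)
        table = read_gwas_table(tmp_path / "t.tsv")
        assert len(table) == 4
        assert table.provenance["dropped_se_nonpositive"] == 1

    def test_duplicate_snp_keeps_smallest_p(self, rng, tmp_path):
        frame = random_gwas_frame(rng, 4)
        dup = frame.iloc[[0]].assign(pval=frame["pval"].iloc[0] / 10, beta=9.0)
        pd.concat([frame, dup]).to_csv(tmp_path / "t.tsv", sep="\t", index=False)
        table = read_gwas_table(tmp_path / "t.tsv")
        assert len(table) == 4
        assert table.records.loc[table.records["snp"] == "rs0", "beta"].iloc[0] == 9.0

    def test_column_map_renames_nonstandard_headers(self, rng, tmp_path):
        frame = random_gwas_frame(rng, 5).rename(columns={"snp": "rsid", "pval": "p"})
        frame.to_csv(tmp_path / "t.tsv", sep="\t", index=False)
        table = read_gwas_table(tmp_path / "t.tsv",
                                column_map={"snp": "rsid", "pval": "p"})
        assert len(table) == 5

    def test_missing_mapped_column_is_named(self, rng, tmp_path):
        random_gwas_frame(rng, 3).to_csv(tmp_path / "t.tsv", sep="\t", index=False)
        with pytest.raises(ColumnMappingError, match="nope"):
            read_gwas_table(tmp_path / "t.tsv", column_map={"beta": "nope"})

    def test_zero_valid_rows_raises(self, rng, tmp_path):
        frame = random_gwas_frame(rng, 3).assign(se=0.0)
        frame.to_csv(tmp_path / "t.tsv", sep="\t", index=False)
        with pytest.raises(EmptyInputError):
            read_gwas_table(tmp_path / "t.tsv")


def brute_force_clump(df, ld, r2_threshold, window_kb):
    """Literal restatement of the greedy rule, kept independent of the
    implementation's vectorized bookkeeping."""
    remaining = df.sort_values(["pval", "chr", "pos", "snp"]).to_dict("records")
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            r for r in remaining
            if not (r["chr"] == best["chr"]
                    and abs(r["pos"] - best["pos"]) <= window_kb * 1000
                    and ld.lookup(best["snp"], r["snp"]) >= r2_threshold)
        ]
    return sorted((k["snp"] for k in kept))


class TestClumping:
    def test_independent_snps_both_kept(self, rng):
        df = random_gwas_frame(rng, 2).assign(chr="1", pos=[100, 5100])
        ld = LdMatrix(["rs0", "rs1"], np.eye(2))
        assert len(greedy_clump(df, ld, 0.001, 10_000)) == 2

    def test_correlated_pair_keeps_smaller_p(self, rng):
        df = random_gwas_frame(rng, 2).assign(
            chr="1", pos=[100, 5100], pval=[1e-9, 1e-10])
        ld = LdMatrix(["rs0", "rs1"], np.array([[1, 0.5], [0.5, 1]]))
        out = greedy_clump(df, ld, 0.001, 10_000)
        assert out["snp"].tolist() == ["rs1"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        df = random_gwas_frame(rng, 10)
        df["chr"] = rng.integers(1, 3, 10).astype(str)
        df["pos"] = rng.integers(1, 30_000_000, 10)
        r2 = rng.uniform(0, 1, (10, 10))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LdMatrix(df["snp"].tolist(), r2)
        got = sorted(greedy_clump(df, ld, 0.3, 10_000)["snp"])
        assert got == brute_force_clump(df, ld, 0.3, 10_000)

    def test_clump_invariants(self, rng):
        df = random_gwas_frame(rng, 30)
        df["chr"] = "1"
        df["pos"] = rng.integers(1, 50_000_000, 30)
        r2 = rng.uniform(0, 1, (30, 30))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LdMatrix(df["snp"].tolist(), r2)
        out = greedy_clump(df, ld, 0.4, 10_000)
        assert set(out["snp"]) <= set(df["snp"])
        assert out["pval"].min() == df["pval"].min()
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                a, b = out.iloc[i], out.iloc[j]
                if a["chr"] == b["chr"] and abs(a["pos"] - b["pos"]) <= 10_000_000:
                    assert ld.lookup(a["snp"], b["snp"]) < 0.4

    def test_missing_snp_in_ld_raises(self, rng):
        df = random_gwas_frame(rng, 3)
        ld = LdMatrix.identity(["rs0", "rs1"])
        with pytest.raises(SnpNotInLdError):
            greedy_clump(df, ld, 0.001, 10_000)


class TestSelectInstruments:
    def test_nothing_significant_gives_empty_table(self, rng):
        table = make_table(random_gwas_frame(rng, 10).assign(pval=0.5))
        assert len(select_instruments(table, AnalysisConfig())) == 0

    def test_defaults_match_conventional_criteria(self):
        cfg = AnalysisConfig()
        assert cfg.instrument_p_threshold == 5e-8
        assert cfg.clump_r2 == 0.001
        assert cfg.clump_window_kb == 10_000

    def test_without_ld_keeps_all_significant(self, rng):
        frame = random_gwas_frame(rng, 10)
        frame.loc[:4, "pval"] = 1e-10
        frame.loc[5:, "pval"] = 0.01
        out = select_instruments(make_table(frame), AnalysisConfig())
        assert len(out) == 5

    def test_filter_then_clump_matches_oracle(self, rng):
        frame = random_gwas_frame(rng, 20)
        frame["pval"] = np.where(np.arange(20) % 2 == 0, 1e-10, 0.5)
        frame["chr"] = "1"
        frame["pos"] = rng.integers(1, 40_000_000, 20)
        r2 = rng.uniform(0, 1, (20, 20))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LdMatrix(frame["snp"].tolist(), r2)
        cfg = AnalysisConfig(clump_r2=0.3)
        got = sorted(select_instruments(make_table(frame), cfg, ld).records["snp"])
        sig = frame[frame["pval"] < cfg.instrument_p_threshold]
        assert got == brute_force_clump(sig, ld, 0.3, cfg.clump_window_kb)


def orientation_oracle(e_row, o_row, band=0.08):
    """Independent restatement of the harmonization rules for one SNP.

    Returns (beta_out, eaf_out) on the exposure orientation, or None when
    the pair must be dropped.
    """
    a1, a2 = e_row["effect_allele"], e_row["other_allele"]
    b1, b2 = o_row["effect_allele"], o_row["other_allele"]
    forms_same = {(a1, a2), (COMP[a1], COMP[a2])}
    forms_swap = {(a2, a1), (COMP[a2], COMP[a1])}
    if (b1, b2) in forms_same:
        beta, eaf = o_row["beta"], o_row["eaf"]
    elif (b1, b2) in forms_swap:
        beta, eaf = -o_row["beta"], 1 - o_row["eaf"]
    else:
        return None
    if COMP[a1] == a2:  # palindromic
        if np.isnan(e_row["eaf"]) or np.isnan(eaf):
            return None
        if abs(e_row["eaf"] - 0.5) <= band or abs(eaf - 0.5) <= band:
            return None
        if (e_row["eaf"] - 0.5) * (eaf - 0.5) <= 0:
            return None
    return beta, eaf


class TestHarmonize:
    def test_identical_coding_is_identity(self, rng):
        frame = random_gwas_frame(rng, 10)
        h = harmonize(make_table(frame, "x"), make_table(frame, "y"))
        np.testing.assert_allclose(h.pairs["beta_out"], h.pairs["beta_exp"])

    def test_swapped_alleles_flip_sign(self, rng):
        frame = random_gwas_frame(rng, 1)
        frame[["effect_allele", "other_allele"]] = [["A", "C"]]
        frame["beta"] = 0.2
        out = frame.copy()
        out[["effect_allele", "other_allele"]] = [["C", "A"]]
        h = harmonize(make_table(frame, "x"), make_table(out, "y"))
        assert h.pairs["beta_out"].iloc[0] == pytest.approx(-0.2)

    def test_allele_swapped_self_is_involution(self, rng):
        """Harmonizing a table against its own swapped copy negates betas."""
        frame = random_gwas_frame(rng, 30)
        out = frame.copy()
        out[["effect_allele", "other_allele"]] = \
            frame[["other_allele", "effect_allele"]].to_numpy()
        out["eaf"] = 1 - frame["eaf"]
        h = harmonize(make_table(frame, "x"), make_table(out, "y"))
        np.testing.assert_allclose(h.pairs["beta_out"], -h.pairs["beta_exp"])

    @pytest.mark.parametrize("seed", range(5))
    def test_randomized_codings_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        frame = random_gwas_frame(rng, 50)
        # randomize outcome coding: swap, strand-flip, both, or mismatch
        out = frame.copy()
        for i in out.index:
            a1, a2 = out.loc[i, ["effect_allele", "other_allele"]]
            mode = rng.integers(0, 5)
            if mode == 1:
                a1, a2 = a2, a1
                out.loc[i, "beta"] = -out.loc[i, "beta"]
                out.loc[i, "eaf"] = 1 - out.loc[i, "eaf"]
            elif mode == 2:
                a1, a2 = COMP[a1], COMP[a2]
            elif mode == 3:
                a1, a2 = COMP[a2], COMP[a1]
                out.loc[i, "beta"] = -out.loc[i, "beta"]
                out.loc[i, "eaf"] = 1 - out.loc[i, "eaf"]
            elif mode == 4:  # incompatible alleles
                a1, a2 = ("A", "C") if {a1, a2} != {"A", "C"} else ("G", "T")
            out.loc[i, ["effect_allele", "other_allele"]] = [a1, a2]
        h = harmonize(make_table(frame, "x"), make_table(out, "y"))
        got = h.pairs.set_index("snp")
        e = frame.set_index("snp")
        o = out.set_index("snp")
        for snp in frame["snp"]:
            expected = orientation_oracle(e.loc[snp], o.loc[snp])
            if expected is None:
                assert snp not in got.index
            else:
                assert got.loc[snp, "beta_out"] == pytest.approx(expected[0])

    def test_ambiguous_palindrome_dropped(self, rng):
        frame = random_gwas_frame(rng, 1)
        frame[["effect_allele", "other_allele"]] = [["A", "T"]]
        frame["eaf"] = 0.45  # inside the 0.42-0.58 ambiguity band
        with pytest.raises(EmptyOverlapError):
            harmonize(make_table(frame, "x"), make_table(frame, "y"))

    def test_decidable_palindrome_kept(self, rng):
        frame = random_gwas_frame(rng, 1)
        frame[["effect_allele", "other_allele"]] = [["A", "T"]]
        frame["eaf"] = 0.2
        h = harmonize(make_table(frame, "x"), make_table(frame, "y"))
        assert len(h) == 1

    def test_empty_intersection_raises(self, rng):
        a = random_gwas_frame(rng, 3)
        b = random_gwas_frame(rng, 3)
        b["snp"] = ["rsX", "rsY", "rsZ"]
        with pytest.raises(EmptyOverlapError):
            harmonize(make_table(a, "x"), make_table(b, "y"))


class TestExcludeOutcomeAssociated:
    def test_removes_only_genomewide_outcome_snps(self, rng):
        frame = random_gwas_frame(rng, 10)
        out = frame.copy()
        out.loc[3, "pval"] = 1e-9
        h = harmonize(make_table(frame, "x"), make_table(out, "y"))
        h2 = exclude_outcome_associated(h, p_threshold=5e-8)
        assert len(h2) == len(h) - 1
        assert "rs3" not in set(h2.pairs["snp"])

    def test_noop_when_no_signal_and_idempotent(self, rng):
        frame = random_gwas_frame(rng, 10)
        out = frame.copy()
        out["pval"] = rng.uniform(0.01, 1, 10)
        h = harmonize(make_table(frame, "x"), make_table(out, "y"))
        h2 = exclude_outcome_associated(h, p_threshold=5e-8)
        assert len(h2) == len(h)
        h3 = exclude_outcome_associated(h2, p_threshold=5e-8)
        assert len(h3) == len(h2)

    def test_matches_brute_force_filter(self, rng):
        frame = random_gwas_frame(rng, 40)
        out = frame.copy()
        out["pval"] = 10.0 ** rng.uniform(-12, 0, 40)
        h = harmonize(make_table(frame, "x"), make_table(out, "y"))
        h2 = exclude_outcome_associated(h, p_threshold=1e-6)
        expected = set(out.loc[out["pval"] >= 1e-6, "snp"])
        assert set(h2.pairs["snp"]) == expected
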