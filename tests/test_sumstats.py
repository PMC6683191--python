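"""Reading, validation, allele alignment, and harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrbattery.errors import (
    ConfigurationError,
    EmptyIntersectionError,
    SumstatFormatError,
    SumstatValidationError,
)
from mrbattery.simulate import SimConfig, simulate_pair
from mrbattery.sumstats import (
    SumstatRecord,
    SumstatTable,
    align_alleles,
    harmonize,
    read_pair,
    read_sumstats,
    write_pair,
    write_sumstats,
)

from conftest import make_table


def rec(variant="rs1", a1="A", a2="G", beta=0.1, info=1.0, eaf=0.3):
    return SumstatRecord(
        variant_id=variant, chrom="1", pos_bp=100, effect_allele=a1,
        other_allele=a2, beta=beta, se=0.02, pvalue=1e-6, info=info,
        n=10_000, eaf=eaf,
    )


class TestReadWrite:
    def test_round_trip_preserves_data_columns(self, tmp_path, small_table):
        path = tmp_path / "t.tsv"
        write_sumstats(small_table, path)
        again = read_sumstats(path, "trait")
        assert len(again) == 5
        pd.testing.assert_frame_equal(again.data, small_table.data)
        # and the re-written bytes are identical
        path2 = tmp_path / "t2.tsv"
        write_sumstats(again, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_gzip_round_trip(self, tmp_path, small_table):
        path = tmp_path / "t.tsv.gz"
        write_sumstats(small_table, path)
        again = read_sumstats(path, "trait")
        pd.testing.assert_frame_equal(again.data, small_table.data)

    def test_missing_column_names_the_column(self, tmp_path, small_table):
        path = tmp_path / "t.tsv"
        write_sumstats(small_table, path)
        text = path.read_text().replace("BETA", "EFFECT")
        path.write_text(text)
        with pytest.raises(SumstatFormatError, match="BETA"):
            read_sumstats(path, "trait")

    def test_zero_se_rejected_with_row_index(self, tmp_path, small_table):
        small_table.data.loc[3, "SE"] = 0.0
        path = tmp_path / "t.tsv"
        write_sumstats(small_table, path)
        with pytest.raises(SumstatValidationError, match="row 3"):
            read_sumstats(path, "trait")

    def test_inconsistent_pvalue_rejected(self, tmp_path, small_table):
        small_table.data.loc[2, "P"] = 0.5  # |beta/se| implies p << 0.5
        path = tmp_path / "t.tsv"
        write_sumstats(small_table, path)
        with pytest.raises(SumstatValidationError, match="row 2"):
            read_sumstats(path, "trait")

    def test_duplicate_variant_ids_rejected(self):
        with pytest.raises(SumstatValidationError, match="duplicate"):
            make_table(snps=("rs1", "rs1", "rs3", "rs4", "rs5"))

    def test_binary_trait_requires_prevalence(self):
        with pytest.raises(ConfigurationError, match="prevalence"):
            make_table(trait_type="binary")

    def test_pair_round_trip(self, tmp_path):
        exposure, outcome, _, _ = simulate_pair(SimConfig(n_snps=50, n_causal=10, n_blocks=10, seed=5))
        pair = harmonize(exposure, outcome)
        path = tmp_path / "pair.tsv"
        write_pair(pair, path)
        again = read_pair(path)
        assert again.n_shared == pair.n_shared
        assert again.n_dropped_palindromic == pair.n_dropped_palindromic
        assert list(again.rows["SNP"]) == list(pair.rows["SNP"])


class TestAlignAlleles:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        res = align_alleles(rec(a1="A", a2="G", beta=0.10), rec(a1="G", a2="A", beta=0.05, eaf=0.3))
        assert res.verdict == "kept"
        assert res.beta_out == -0.05
        assert res.eaf_out == pytest.approx(0.7)

    def test_same_alleles_kept_unchanged(self):
        res = align_alleles(rec(a1="A", a2="G"), rec(a1="A", a2="G", beta=0.05))
        assert (res.verdict, res.beta_out) == ("kept", 0.05)

    def test_reverse_complement_match(self):
        res = align_alleles(rec(a1="A", a2="G"), rec(a1="T", a2="C", beta=0.05))
        assert (res.verdict, res.beta_out) == ("kept", 0.05)

    def test_reverse_complement_swapped_flips(self):
        res = align_alleles(rec(a1="A", a2="G"), rec(a1="C", a2="T", beta=0.05))
        assert (res.verdict, res.beta_out) == ("kept", -0.05)

    @pytest.mark.parametrize("a1,a2", [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")])
    def test_palindromic_pairs_excluded(self, a1, a2):
        assert align_alleles(rec(a1=a1, a2=a2), rec(a1=a1, a2=a2)).verdict == "palindromic"

    def test_low_info_excluded_on_either_side(self):
        assert align_alleles(rec(), rec(info=0.85)).verdict == "low_info"
        assert align_alleles(rec(info=0.85), rec()).verdict == "low_info"
        assert align_alleles(rec(info=0.9), rec(info=0.9)).verdict == "kept"

    def test_incompatible_allele_sets_mismatch(self):
        assert align_alleles(rec(a1="A", a2="G"), rec(a1="A", a2="C")).verdict == "allele_mismatch"

    def test_palindromic_takes_precedence_over_low_info(self):
        res = align_alleles(rec(a1="A", a2="T", info=0.5), rec(a1="A", a2="T", info=0.5))
        assert res.verdict == "palindromic"


class TestHarmonize:
    def test_intersection_and_counters(self):
        exp = make_table(snps=("rs1", "rs2", "rs3", "rs4", "rs5"))
        out = make_table(snps=("rs3", "rs4", "rs5", "rs6", "rs7"), a1="GCTAA", a2="ATCGG")
        # shared: rs3 (G/A vs G/A), rs4 (C/T vs C/T), rs5 (T/C vs T/C)
        pair = harmonize(exp, out)
        assert pair.n_shared == 3
        assert pair.n_retained == 3

    def test_palindromic_shared_variant_counted(self):
        exp = make_table(snps=("rs1", "rs2", "rs3"), a1="AAG", a2="GTA")  # rs2 is A/T
        out = make_table(snps=("rs1", "rs2", "rs3"), a1="AAG", a2="GTA")
        pair = harmonize(exp, out)
        assert pair.n_retained == 2
        assert pair.n_dropped_palindromic == 1
        assert pair.n_shared == 3

    def test_self_harmonization_is_identity(self, small_table):
        pair = harmonize(small_table, small_table)
        np.testing.assert_array_equal(pair.rows["beta_out"], pair.rows["beta_exp"])

    def test_empty_intersection_raises(self):
        exp = make_table(snps=("rs1", "rs2", "rs3", "rs4", "rs5"))
        out = make_table(snps=("rs6", "rs7", "rs8", "rs9", "rs10"))
        with pytest.raises(EmptyIntersectionError):
            harmonize(exp, out)

    def test_rows_sorted_by_position(self):
        exposure, outcome, _, _ = simulate_pair(SimConfig(n_snps=80, n_causal=20, n_blocks=20, seed=9))
        exposure.data = exposure.data.sample(frac=1, random_state=0).reset_index(drop=True)
        pair = harmonize(exposure, outcome)
        assert pair.rows["BP"].is_monotonic_increasing

    def test_missing_cm_imputed_from_bp(self, small_table):
        with pytest.warns(UserWarning, match="1 cM per Mb"):
            pair = harmonize(small_table, small_table)
        np.testing.assert_allclose(pair.rows["CM"], pair.rows["BP"] / 1e6)

    def test_drop_accounting_on_contaminated_pair(self):
        exposure, outcome, _, _ = simulate_pair(
            SimConfig(n_snps=400, n_causal=50, n_blocks=50,
                      palindromic_frac=0.2, low_info_frac=0.15, seed=11)
        )
        pair = harmonize(exposure, outcome)
        assert pair.n_shared == 400
        assert (
            pair.n_retained + pair.n_dropped_palindromic
            + pair.n_dropped_info + pair.n_dropped_mismatch
        ) == 400
        assert pair.n_dropped_palindromic == 80  # exact designed fraction

    def test_info_filter_removes_all_low_info_records(self):
        exposure, outcome, _, _ = simulate_pair(
            SimConfig(n_snps=300, n_causal=30, n_blocks=30, low_info_frac=0.2,
                      palindromic_frac=0.0, seed=12)
        )
        pair = harmonize(exposure, outcome)
        kept = set(pair.rows["SNP"])
        for table in (exposure, outcome):
            low = set(table.data.loc[table.data["INFO"] < 0.9, "SNP"])
            assert not (kept & low)


class TestHarmonizationInvariances:
    """Strand and allele-labelling transformations must not change results."""

    @pytest.fixture
    def pair_tables(self):
        return simulate_pair(SimConfig(n_snps=200, n_causal=40, n_blocks=40,
                                       palindromic_frac=0.1, low_info_frac=0.1, seed=21))[:2]

    def test_strand_flip_invariance(self, pair_tables):
        exposure, outcome = pair_tables
        rng = np.random.default_rng(0)
        flipped = outcome.data.copy()
        mask = rng.random(len(flipped)) < 0.5
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        flipped.loc[mask, "A1"] = flipped.loc[mask, "A1"].map(comp)
        flipped.loc[mask, "A2"] = flipped.loc[mask, "A2"].map(comp)
        out2 = SumstatTable(outcome.trait_name, "binary", flipped,
                            prevalence=outcome.prevalence)
        base = harmonize(exposure, outcome)
        alt = harmonize(exposure, out2)
        pd.testing.assert_frame_equal(base.rows, alt.rows)
        assert base.n_dropped_palindromic == alt.n_dropped_palindromic

    def test_effect_allele_swap_invariance(self, pair_tables):
        exposure, outcome = pair_tables
        rng = np.random.default_rng(1)
        swapped = outcome.data.copy()
        mask = rng.random(len(swapped)) < 0.5
        a1 = swapped.loc[mask, "A1"].copy()
        swapped.loc[mask, "A1"] = swapped.loc[mask, "A2"]
        swapped.loc[mask, "A2"] = a1
        swapped.loc[mask, "BETA"] = -swapped.loc[mask, "BETA"]
        swapped.loc[mask, "EAF"] = 1.0 - swapped.loc[mask, "EAF"]
        out2 = SumstatTable(outcome.trait_name, "binary", swapped,
                            prevalence=outcome.prevalence)
        base = harmonize(exposure, outcome)
        alt = harmonize(exposure, out2)
        pd.testing.assert_frame_equal(base.rows, alt.rows)
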