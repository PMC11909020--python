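"""Summary parsing, the Hardy-Weinberg exact test, variant filters and
allele harmonization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prsdiff.config import QCThresholds
from prsdiff.containers import GenotypeMatrix
from prsdiff.errors import ConfigurationError, ValidationError
from prsdiff.qc import (
    filter_samples,
    filter_variants,
    harmonize_alleles,
    hwe_exact_test,
    parse_sumstats,
    variant_stats,
)


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Independent exact enumeration using factorials directly."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)

    def w(h):
        aa = (n_A - h) // 2
        bb = (n_a - h) // 2
        return (math.factorial(n)
                // (math.factorial(aa) * math.factorial(h) * math.factorial(bb))
                * 2 ** h)

    weights = {h: w(h) for h in range(rare % 2, rare + 1, 2)}
    w_obs = weights[n_Aa]
    return sum(x for x in weights.values() if x <= w_obs) / sum(weights.values())


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_two_sample_enumeration(self):
        # alleles 2+2: het counts {0, 2} with weights 2 and 4 -> p = 2/6
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3, abs=1e-15)

    def test_against_enumeration_oracle(self):
        assert hwe_exact_test(57, 14, 50) == pytest.approx(
            hwe_enumeration_oracle(57, 14, 50), abs=1e-12)

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValidationError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValidationError):
            hwe_exact_test(-1, 2, 3)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_symmetry_and_range(self, a, h, b):
        if a + h + b == 0:
            return
        p = hwe_exact_test(a, h, b)
        assert 0 < p <= 1
        assert p == hwe_exact_test(b, h, a)

    def test_single_configuration_returns_one(self):
        # one copy of the rare allele: the heterozygote is forced
        assert hwe_exact_test(10, 1, 0) == 1.0


class TestParseSumstats:
    def _write(self, tmp_path, rows, header):
        path = tmp_path / "ss.tsv"
        path.write_text("\t".join(header) + "\n"
                        + "\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        return path

    HEADER = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
              "logOR", "p_value", "info"]

    def test_well_formed_rows_all_parse(self, tmp_path):
        rows = [["rs1", 1, 100, "A", "G", 0.1, 0.5, 0.9],
                ["rs2", 2, 200, "C", "T", -0.2, 0.01, 0.8],
                ["rs3", 3, 300, "G", "A", 0.0, 1.0, 1.0]]
        df = parse_sumstats(self._write(tmp_path, rows, self.HEADER))
        assert len(df) == 3
        assert df.attrs["bad_rows"] == []

    def test_or_column_is_logged(self, tmp_path):
        header = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                  "OR", "p_value", "info"]
        rows = [["rs1", 1, 100, "A", "G", 2.0, 0.5, 0.9]]
        df = parse_sumstats(self._write(tmp_path, rows, header))
        assert df["logOR"].iloc[0] == pytest.approx(np.log(2.0))

    def test_zero_pvalue_row_rejected(self, tmp_path):
        rows = [["rs1", 1, 100, "A", "G", 0.1, 0.0, 0.9],
                ["rs2", 2, 200, "C", "T", 0.1, 0.5, 0.9]]
        df = parse_sumstats(self._write(tmp_path, rows, self.HEADER),
                            max_bad_fraction=0.6)
        assert list(df["variant_id"]) == ["rs2"]
        assert df.attrs["bad_rows"] == [1]

    def test_missing_column_is_configuration_error(self, tmp_path):
        header = self.HEADER[:-1]
        rows = [["rs1", 1, 100, "A", "G", 0.1, 0.5]]
        with pytest.raises(ConfigurationError):
            parse_sumstats(self._write(tmp_path, rows, header))

    def test_too_many_bad_rows_aborts(self, tmp_path):
        rows = [["rs1", 1, 100, "A", "A", 0.1, 0.5, 0.9],
                ["rs2", 2, 200, "C", "T", 0.1, 0.5, 0.9]]
        with pytest.raises(ValidationError):
            parse_sumstats(self._write(tmp_path, rows, self.HEADER),
                           max_bad_fraction=0.1)


def _variant_row(vid, chrom=1, pos=100, ref="A", alt="G", **kw):
    row = dict(variant_id=vid, chrom=str(chrom), pos=pos, ref_allele=ref,
               alt_allele=alt, call_rate=1.0, maf=0.3, hwe_p=1.0,
               imputation_quality=0.99, is_indel=len(ref) != 1 or len(alt) != 1)
    row.update(kw)
    return row


class TestFilterVariants:
    def test_ambiguous_pair_removed(self):
        v = pd.DataFrame([_variant_row("rs1", ref="A", alt="T"),
                          _variant_row("rs2", pos=200)])
        kept, report = filter_variants(v)
        assert list(kept["variant_id"]) == ["rs2"]
        assert report.counts == {"ambiguous": 1}

    def test_all_passing_is_identity(self):
        v = pd.DataFrame([_variant_row(f"rs{i}", pos=100 * (i + 1))
                          for i in range(5)])
        kept, report = filter_variants(v)
        assert len(kept) == 5 and report.counts == {}
        assert report.variants_in == report.variants_out == 5

    def test_first_filter_wins_attribution(self):
        # duplicated AND ambiguous: charged to the duplicate filter
        v = pd.DataFrame([_variant_row("rs1", ref="C", alt="G"),
                          _variant_row("rs1", ref="C", alt="G"),
                          _variant_row("rs2", pos=300)])
        kept, report = filter_variants(v)
        assert report.counts == {"duplicate": 2}

    def test_threshold_filters_fire(self):
        v = pd.DataFrame([
            _variant_row("rs1", call_rate=0.5, pos=100),
            _variant_row("rs2", hwe_p=1e-7, pos=200),
            _variant_row("rs3", maf=1e-4, pos=300),
            _variant_row("rs4", imputation_quality=0.8, pos=400),
            _variant_row("rs5", chrom="X", pos=500),
            _variant_row("rs6", pos=600),
        ])
        kept, report = filter_variants(v)
        assert list(kept["variant_id"]) == ["rs6"]
        assert report.counts == {"non_autosomal": 1, "low_call_rate": 1,
                                 "hwe_fail": 1, "low_maf": 1,
                                 "low_imputation_quality": 1}

    def test_idempotent(self, small_qc):
        stats, ss = small_qc
        kept, _ = filter_variants(stats, ss)
        kept2, report2 = filter_variants(kept, ss)
        assert len(kept2) == len(kept) and report2.counts == {}

    def test_planted_violations_exactly_removed(self, small_cohort):
        _, cohort = small_cohort
        stats = variant_stats(cohort["genotypes"], cohort["variants"])
        stats["chrom"] = stats["chrom"].astype(str)
        kept, report = filter_variants(stats, cohort["sumstats"])
        planted = cohort["variants"].set_index("variant_id")["planted_class"]
        # removed set == planted set (duplicates share ids -> compare multisets)
        removed = report.reasons
        assert sorted(removed["variant_id"]) == sorted(
            planted[planted != ""].index)
        class_of = dict(zip(cohort["variants"]["variant_id"],
                            cohort["variants"]["planted_class"]))
        for _, row in removed.iterrows():
            assert class_of[row["variant_id"]] == row["reason"]
        assert not kept["variant_id"].isin(
            planted[planted != ""].index).any()


def test_filter_samples_by_call_rate():
    d = np.ones((3, 4))
    d[0, :3] = np.nan  # 25% call rate
    g = GenotypeMatrix(d, ["a", "b", "c"], [f"v{i}" for i in range(4)])
    kept, removed = filter_samples(g, min_call_rate=0.6)
    assert removed == ["a"] and kept.samples == ["b", "c"]


class TestHarmonizeAlleles:
    TARGET = pd.DataFrame([
        dict(variant_id="rs1", ref_allele="A", alt_allele="G"),
    ])

    def _ss(self, ea, oa, logor=0.3):
        return pd.DataFrame([dict(variant_id="rs1", effect_allele=ea,
                                  other_allele=oa, logOR=logor, p_value=0.1)])

    @pytest.mark.parametrize("ea,oa,expected", [
        ("G", "A", +0.3),    # direct
        ("A", "G", -0.3),    # effect allele is target ref -> sign flip
        ("C", "T", +0.3),    # strand complement of direct
        ("T", "C", -0.3),    # strand complement of swap
    ])
    def test_orientation_truth_table(self, ea, oa, expected):
        w, counts = harmonize_alleles(self._ss(ea, oa), self.TARGET)
        assert len(w) == 1
        assert w["weight"].iloc[0] == pytest.approx(expected)
        assert w["aligned_allele"].iloc[0] == "G"

    def test_mismatched_pair_dropped(self):
        w, counts = harmonize_alleles(self._ss("A", "C"), self.TARGET)
        assert len(w) == 0 and counts["dropped_unmatched"] == 1

    def test_ambiguous_pair_dropped(self):
        target = pd.DataFrame([dict(variant_id="rs1", ref_allele="A",
                                    alt_allele="T")])
        w, counts = harmonize_alleles(self._ss("A", "T"), target)
        assert len(w) == 0 and counts["dropped_ambiguous"] == 1

    def test_double_application_restores_signs(self, small_qc):
        stats, ss = small_qc
        kept, _ = filter_variants(stats, ss)
        w1, _ = harmonize_alleles(ss, kept)
        # re-express the harmonized weights as a summary table aligned to
        # the target alt allele, then harmonize again: signs must persist
        ss2 = kept.merge(w1, on="variant_id")
        ss2 = pd.DataFrame(dict(variant_id=ss2["variant_id"],
                                effect_allele=ss2["alt_allele"],
                                other_allele=ss2["ref_allele"],
                                logOR=ss2["weight"], p_value=ss2["p_value"]))
        w2, _ = harmonize_alleles(ss2, kept)
        merged = w1.merge(w2, on="variant_id", suffixes=("_1", "_2"))
        assert len(merged) == len(w1)
        np.testing.assert_allclose(merged["weight_1"], merged["weight_2"])
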