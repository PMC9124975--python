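"""Normalization, the dual-reference screen, categories and conservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fes2red.transcripts import (
    DERecord,
    FilterCriteria,
    abundance_fraction,
    abundance_fractions,
    categorize_gene,
    conservation_tally,
    median_of_ratios_normalize,
    upregulated_screen,
)


def record(gene="g", abundance=100.0, lfc1=1.0, p1=0.01, lfc2=1.0, p2=0.01):
    return DERecord(
        gene=gene, mean_norm_abundance=abundance,
        lfc_vs_ref1=lfc1, p_vs_ref1=p1, lfc_vs_ref2=lfc2, p_vs_ref2=p2,
    )


class TestNormalization:
    def test_identical_samples_have_unit_size_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        sf, norm = median_of_ratios_normalize(counts)
        assert np.allclose(sf, 1.0)
        assert np.allclose(norm, counts)

    def test_single_gene_two_samples(self):
        # geometric mean 4; ratios 2/4 and 8/4
        counts = pd.DataFrame({"s1": [2], "s2": [8]})
        sf, _ = median_of_ratios_normalize(counts)
        assert sf["s1"] == pytest.approx(0.5)
        assert sf["s2"] == pytest.approx(2.0)

    def test_scaled_sample_absorbs_the_scale(self):
        """Doubling one sample gene-wise: size factors share the gmean shift.

        On a 3-gene toy matrix (s2 = 2 * s1) the per-gene geometric means
        are sqrt(2) * s1, so sf(s1) = 1/sqrt(2) and sf(s2) = sqrt(2); the
        normalized matrices coincide.
        """
        counts = pd.DataFrame({"s1": [10, 100, 1000], "s2": [20, 200, 2000]})
        sf, norm = median_of_ratios_normalize(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert np.allclose(norm["s1"], norm["s2"])

    def test_idempotence(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.poisson(50, size=(40, 6)) + 1,
            columns=[f"s{i}" for i in range(6)],
        )
        counts["s0"] *= 3
        _, norm = median_of_ratios_normalize(counts)
        sf2, _ = median_of_ratios_normalize(norm)
        assert np.allclose(sf2, 1.0, atol=1e-12)

    def test_no_common_positive_gene_is_an_error(self):
        counts = pd.DataFrame({"s1": [5, 0], "s2": [0, 5]})
        with pytest.raises(ValueError, match="normalization impossible"):
            median_of_ratios_normalize(counts)


class TestAbundanceFraction:
    def test_single_gene_is_unity(self):
        norm = pd.DataFrame({"a": [7.0], "b": [9.0]}, index=["g1"])
        assert abundance_fraction(norm, ["a", "b"], "g1") == 1.0

    def test_two_gene_arithmetic(self):
        norm = pd.DataFrame(
            {"a": [1.0, 199.0], "b": [1.0, 199.0]}, index=["g1", "g2"]
        )
        assert abundance_fraction(norm, ["a", "b"], "g1") == pytest.approx(
            0.005
        )

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        norm = pd.DataFrame(
            rng.uniform(0, 100, size=(30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=list("abcd"),
        )
        fr = abundance_fractions(norm, ["a", "b"])
        assert fr.sum() == pytest.approx(1.0)

    def test_missing_gene_raises(self):
        norm = pd.DataFrame({"a": [1.0]}, index=["g1"])
        with pytest.raises(KeyError):
            abundance_fraction(norm, ["a"], "nope")


class TestScreen:
    def test_empty_input_empty_output(self):
        assert upregulated_screen([], fractions={}) == set()

    def test_boundary_lfc_excluded(self):
        """LFC exactly 0.5 fails the strict > threshold."""
        recs = [record("edge", lfc1=0.5), record("pass", lfc1=0.51)]
        hits = upregulated_screen(recs)
        assert hits == {"pass"}

    def test_boundary_p_excluded(self):
        recs = [record("edge", p1=0.05), record("pass", p1=0.049)]
        assert upregulated_screen(recs) == {"pass"}

    def test_both_references_required(self):
        recs = [
            record("only1", p2=0.5),
            record("only2", p1=0.5),
            record("both"),
        ]
        assert upregulated_screen(recs) == {"both"}

    def test_abundance_threshold_applies(self):
        # fractions ~3e-6 and ~1: only the abundant gene clears 5e-5
        recs = [record("tiny", abundance=1.0), record("big", abundance=3e5)]
        assert upregulated_screen(recs) == {"big"}

    def test_explicit_fractions_override_derived(self):
        recs = [record("g1", abundance=100.0)]
        hits = upregulated_screen(recs, fractions={"g1": 1e-6})
        assert hits == set()

    @settings(derandomize=True, max_examples=25)
    @given(
        p_max=st.floats(min_value=0.001, max_value=0.05),
        lfc_min=st.floats(min_value=0.5, max_value=2.0),
        tighten=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_anti_monotone_in_thresholds(self, p_max, lfc_min, tighten):
        """Tightening any threshold never adds genes."""
        rng = np.random.default_rng(11)
        recs = [
            record(
                f"g{i}",
                abundance=float(rng.uniform(0.1, 100)),
                lfc1=float(rng.normal(0.5, 1)),
                p1=float(rng.uniform(0, 0.2)),
                lfc2=float(rng.normal(0.5, 1)),
                p2=float(rng.uniform(0, 0.2)),
            )
            for i in range(60)
        ]
        loose = FilterCriteria(p_max=p_max, lfc_min=lfc_min)
        tight = FilterCriteria(
            p_max=p_max * (1 - tighten / 2), lfc_min=lfc_min + tighten
        )
        assert upregulated_screen(recs, tight) <= upregulated_screen(
            recs, loose
        )

    def test_bh_adjustment_only_shrinks_the_hit_set(self):
        rng = np.random.default_rng(5)
        recs = [
            record(
                f"g{i}",
                p1=float(rng.uniform(0, 0.1)),
                p2=float(rng.uniform(0, 0.1)),
            )
            for i in range(40)
        ]
        raw = upregulated_screen(recs, FilterCriteria())
        adjusted = upregulated_screen(recs, FilterCriteria(adjust_p=True))
        assert adjusted <= raw


class TestCategorize:
    @pytest.mark.parametrize(
        "p1, p2, lfc1, lfc2, expected",
        [
            (0.01, 0.01, 1.0, 0.8, "blue"),
            (0.01, 0.01, 0.3, 0.9, "green"),  # significant but small LFC
            (0.20, 0.01, 0.9, 0.9, "yellow"),  # upregulated, not significant
            (0.20, 0.30, -0.2, 0.4, "white"),
            (0.01, 0.01, 0.5, 0.5, "green"),  # boundary LFC is not blue
        ],
    )
    def test_category_rules(self, p1, p2, lfc1, lfc2, expected):
        rec = record("g", p1=p1, p2=p2, lfc1=lfc1, lfc2=lfc2)
        assert categorize_gene(rec) == expected

    @settings(derandomize=True, max_examples=40)
    @given(
        p1=st.floats(min_value=0, max_value=1),
        p2=st.floats(min_value=0, max_value=1),
        lfc1=st.floats(min_value=-3, max_value=3),
        lfc2=st.floats(min_value=-3, max_value=3),
    )
    def test_every_record_gets_exactly_one_category(self, p1, p2, lfc1, lfc2):
        rec = record("g", p1=p1, p2=p2, lfc1=lfc1, lfc2=lfc2)
        assert categorize_gene(rec) in {"blue", "green", "yellow", "white"}

    def test_blue_genes_pass_the_screen_when_abundant(self):
        recs = [record(f"g{i}", abundance=10.0) for i in range(5)]
        hits = upregulated_screen(recs)
        for rec in recs:
            if categorize_gene(rec) == "blue":
                assert rec.gene in hits


class TestConservation:
    def test_all_present_counts_everything(self):
        genes = [f"g{i}" for i in range(30)]
        presence = pd.DataFrame(
             np.ones((30, 4), dtype=int), index=genes,
            columns=[f"G{i}" for i in range(4)],
        )
        counts, n_all = conservation_tally(genes, presence)
        assert (counts == 4).all()
        assert n_all == 30

    def test_nineteen_of_thirty_structure(self):
        """A 30 x 4 matrix built with 19 fully conserved rows tallies 19."""
        genes = [f"g{i:02d}" for i in range(30)]
        mat = np.ones((30, 4), dtype=int)
        mat[19:, 0] = 0  # 11 genes missing from the first genome
        presence = pd.DataFrame(mat, index=genes, columns=list("ABCD"))
        _, n_all = conservation_tally(genes, presence)
        assert n_all == 19

    def test_empty_gene_set(self):
        presence = pd.DataFrame({"A": [1]}, index=["g0"])
        counts, n_all = conservation_tally([], presence)
        assert len(counts) == 0 and n_all == 0

    def test_absent_gene_raises(self):
        presence = pd.DataFrame({"A": [1]}, index=["g0"])
        with pytest.raises(KeyError):
            conservation_tally(["missing"], presence)


class TestRecordValidation:
    def test_p_value_out_of_range(self):
        with pytest.raises(ValueError, match="p_vs_ref1"):
            record(p1=1.5)

    def test_nan_lfc_rejected(self):
        with pytest.raises(ValueError):
            record(lfc2=float("nan"))

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            FilterCriteria(p_max=0.0)
        with pytest.raises(ValueError):
            FilterCriteria(abundance_fraction_min=1.0)
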