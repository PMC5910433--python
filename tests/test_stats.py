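import numpy as np
import pandas as pd
import pytest

from oracles import fisher_by_enumeration, hypergeom_tail
from phylofam import (
    copy_number_pca,
    fisher_exact_2x2,
    hypergeom_enrichment,
    presence_percent,
    proteome_percent,
    ssp_filter,
)
from phylofam.stats import AnnotationTable


def annot_table(rows):
    df = pd.DataFrame(
        rows, columns=["protein_id", "species", "length", "signal_peptide", "terms"]
    )
    df["terms"] = df["terms"].map(frozenset)
    return AnnotationTable(df.set_index("protein_id", drop=False))


class TestHypergeomEnrichment:
    def test_textbook_tail(self):
        # N=10, K=5, n=4, k=4 -> 5/210
        term_sets = {f"u{i}": {"T"} if i < 5 else set() for i in range(10)}
        res = hypergeom_enrichment(
            {"u0", "u1", "u2", "u3"}, set(term_sets), term_sets
        )
        assert res[0].term == "T"
        assert res[0].p_raw == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_sample_successes_gives_p_one(self):
        term_sets = {"a": {"T"}, "b": set(), "c": set()}
        res = hypergeom_enrichment({"b", "c"}, {"a", "b", "c"}, term_sets)
        assert res[0].p_raw == 1.0

    def test_bonferroni_multiplies_by_testable_terms(self):
        term_sets = {
            "a": {"T1", "T2"}, "b": {"T3"}, "c": {"T4", "T5"}, "d": set(),
        }
        res = hypergeom_enrichment({"a"}, set(term_sets), term_sets)
        assert all(r.m == 5 for r in res)
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * 5))

    def test_sample_must_be_subset(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment({"zz"}, {"a"}, {"a": set()})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        units = [f"u{i}" for i in range(12)]
        term_sets = {
            u: {t for t in ("X", "Y", "Z") if rng.random() < 0.4} for u in units
        }
        sample = set(rng.choice(units, size=5, replace=False))
        for r in hypergeom_enrichment(sample, set(units), term_sets):
            assert r.p_raw == pytest.approx(
                hypergeom_tail(r.N, r.K, r.n, r.k), rel=1e-9
            )

    def test_sorted_by_adjusted_p(self):
        term_sets = {f"u{i}": ({"HOT"} if i < 4 else {"COLD"}) for i in range(10)}
        res = hypergeom_enrichment(
            {"u0", "u1", "u2", "u3"}, set(term_sets), term_sets
        )
        assert res[0].term == "HOT"
        ps = [r.p_bonferroni for r in res]
        assert ps == sorted(ps)


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(2 / 184756, rel=1e-9)

    def test_margin_symmetry(self):
        assert fisher_exact_2x2(7, 2, 3, 9) == pytest.approx(
            fisher_exact_2x2(9, 3, 2, 7), rel=1e-9
        )

    def test_matches_enumeration_on_small_tables(self):
        for a, b, c, d in [(1, 2, 3, 4), (0, 5, 5, 0), (2, 2, 2, 2), (4, 0, 1, 3)]:
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_by_enumeration(a, b, c, d), rel=1e-7
            )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)


class TestSspFilter:
    def test_boundaries_and_flags(self):
        annot = annot_table(
            [
                ("in_mid", "S1", 150, True, set()),
                ("at_min", "S1", 80, True, set()),
                ("at_max", "S1", 300, True, set()),
                ("too_long", "S1", 301, True, set()),
                ("too_short", "S1", 79, True, set()),
                ("no_signal", "S1", 150, False, set()),
            ]
        )
        ids, fraction = ssp_filter(annot)
        assert ids == {"in_mid", "at_min", "at_max"}
        assert fraction == 50.0

    def test_fraction_rounding(self):
        rows = [(f"p{i}", "S1", 100, i < 1, set()) for i in range(3)]
        _, fraction = ssp_filter(annot_table(rows))
        assert fraction == 33.3


class TestPercentages:
    @pytest.mark.parametrize(
        "found,searched,expected",
        [(93, 127, 73), (89, 127, 70), (28, 31, 90), (26, 31, 84), (0, 10, 0)],
    )
    def test_presence_percent(self, found, searched, expected):
        assert presence_percent(found, searched) == expected

    def test_presence_percent_half_up(self):
        assert presence_percent(1, 8) == 13  # 12.5 rounds up

    def test_presence_percent_validation(self):
        with pytest.raises(ValueError):
            presence_percent(1, 0)
        with pytest.raises(ValueError):
            presence_percent(5, 4)

    def test_proteome_percent(self):
        assert proteome_percent(1912, 22766) == 8.4
        assert proteome_percent(1543, 18750) == 8.2


class TestCopyNumberPCA:
    def test_single_varying_family_concentrates_variance(self):
        profile = pd.DataFrame(
            {"famA": [1, 5, 9, 2], "famB": [3, 3, 3, 3], "famC": [7, 7, 7, 7]},
            index=["g1", "g2", "g3", "g4"],
        )
        res = copy_number_pca(profile)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_duplicate_genome_rows_identical_scores(self):
        rng = np.random.default_rng(0)
        profile = pd.DataFrame(
            rng.integers(0, 20, size=(5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"f{i}" for i in range(6)],
        )
        profile.loc["g4"] = profile.loc["g0"]
        res = copy_number_pca(profile)
        assert np.allclose(res.scores.loc["g4"], res.scores.loc["g0"])

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        profile = pd.DataFrame(
            rng.integers(0, 30, size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"f{i}" for i in range(6)],
        )
        res = copy_number_pca(profile)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.variance_fraction) <= 1e-12).all()

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        profile = pd.DataFrame(
            rng.integers(0, 10, size=(6, 4)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"f{i}" for i in range(4)],
        )
        shifted = profile.copy()
        shifted["f1"] = shifted["f1"] + 100
        a = copy_number_pca(profile)
        b = copy_number_pca(shifted)
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy())
        assert np.allclose(a.variance_fraction, b.variance_fraction)

    def test_constant_matrix_rejected(self):
        profile = pd.DataFrame(
            {"f1": [2, 2, 2], "f2": [3, 3, 3]}, index=["a", "b", "c"]
        )
        with pytest.raises(ValueError, match="constant"):
            copy_number_pca(profile)

    def test_scaled_mode_drops_constant_columns(self):
        profile = pd.DataFrame(
            {"f1": [1, 2, 3], "f2": [5, 5, 5], "f3": [9, 1, 4]},
            index=["a", "b", "c"],
        )
        res = copy_number_pca(profile, scale=True)
        assert list(res.loadings.index) == ["f1", "f3"]


class TestAnnotationTableIO:
    def test_tsv_roundtrip(self, tmp_path):
        annot = annot_table(
            [
                ("S1|p1", "S1", 120, True, {"T1", "T2"}),
                ("S2|p2", "S2", 400, False, set()),
            ]
        )
        path = tmp_path / "annot.tsv"
        annot.to_tsv(path)
        back = AnnotationTable.from_tsv(path)
        assert list(back.df.protein_id) == list(annot.df.protein_id)
        assert list(back.df.terms) == list(annot.df.terms)
        assert list(back.df.signal_peptide) == [True, False]

    def test_validation(self):
        with pytest.raises(ValueError, match="length"):
            annot_table([("p", "S", 0, True, set())])
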