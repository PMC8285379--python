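from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pfcnet import scoring
from pfcnet.scoring import (
    classify_dark,
    dark_abundance_test,
    functional_homogeneity,
    rank_sum_test,
    score_pfc,
    taxonomy_profile,
)

from _oracles import exact_ranksum_pvalue
from conftest import make_protein, make_taxonomy


class TestFunctionalHomogeneity:
    @pytest.mark.parametrize(
        "term_sets,expected",
        [
            ([{"K00001"}] * 3, 1.0),                       # all share one term
            ([{"A"}, {"B"}, {"C"}, {"D"}], 0.0),           # all distinct
            ([{"A"}, {"A"}, {"B"}, {"B"}], 0.5),           # 1 - 2/4
            ([set(), set()], None),                         # no annotation -> missing
            ([{"A"}, set(), set()], 1.0),                   # single unique term
            ([{"A", "B"}, {"C", "D"}, set()], 0.0),        # floored at 0 (4 terms, 3 proteins)
        ],
    )
    def test_examples(self, term_sets, expected):
        assert functional_homogeneity(term_sets) == expected

    def test_single_protein_is_error(self):
        with pytest.raises(ValueError):
            functional_homogeneity([{"A"}])

    @given(
        st.lists(
            st.sets(st.sampled_from([f"K{i}" for i in range(12)]), max_size=3),
            min_size=2,
            max_size=10,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_score_bounds_and_extremes(self, term_sets):
        score = functional_homogeneity(term_sets)
        unique = set().union(*term_sets) if term_sets else set()
        if not unique:
            assert score is None
        else:
            assert 0.0 <= score <= 1.0
            assert (score == 1.0) == (len(unique) == 1)
            assert (score == 0.0) == (len(unique) >= len(term_sets) > 1)


class TestTaxonomyProfile:
    def test_single_mag_is_homogeneous_everywhere(self):
        tax = {"M1": make_taxonomy("M1")}
        profile, mixes = taxonomy_profile(["M1", "M1", "M1"], tax)
        assert all(profile[r].single_taxon for r in profile)
        assert not mixes

    def test_two_phyla_not_single(self):
        tax = {
            "M1": make_taxonomy("M1", phylum="Proteobacteria"),
            "M2": make_taxonomy("M2", phylum="Bacteroidetes"),
        }
        profile, _ = taxonomy_profile(["M1", "M2"], tax)
        assert profile["phylum"].single_taxon is False

    def test_unannotated_below_phylum_gives_missing_summaries(self):
        tax = {"M1": make_taxonomy("M1", depth="phylum")}
        profile, _ = taxonomy_profile(["M1", "M1"], tax)
        assert profile["phylum"].single_taxon is True
        for rank in ("class", "order", "family", "genus"):
            assert profile[rank].single_taxon is None
            assert profile[rank].n_annotated_proteins == 0


class TestClassifyDark:
    def _scores(self, kegg, eggnog, depth):
        tax = {"M1": make_taxonomy("M1", depth=depth)}
        members = [
            make_protein("p1", "M1", kegg=kegg, eggnog=eggnog),
            make_protein("p2", "M1"),
        ]
        return score_pfc(1, members, tax)

    def test_dark_when_unannotated_and_phylum_only(self):
        assert self._scores((), (), "phylum").is_dark

    def test_kegg_annotation_flips_dark(self):
        assert not self._scores(("K00001",), (), "phylum").is_dark

    def test_class_level_taxonomy_flips_dark(self):
        assert not self._scores((), (), "class").is_dark

    def test_adding_annotation_is_monotone(self):
        # any single added annotation can only move dark -> not-dark
        base = self._scores((), (), "phylum")
        assert base.is_dark
        for kwargs in ({"kegg": ("K1",)}, {"eggnog": ("d",)}):
            tax = {"M1": make_taxonomy("M1", depth="phylum")}
            members = [make_protein("p1", "M1", **kwargs), make_protein("p2", "M1")]
            assert not score_pfc(1, members, tax).is_dark


class TestHomogeneityTag:
    def test_low_in_both_databases_is_tagged(self):
        tax = {"M1": make_taxonomy("M1")}
        members = [
            make_protein(f"p{i}", "M1", kegg={f"K{i}"}, eggnog={f"d{i}"})
            for i in range(4)
        ]
        s = score_pfc(1, members, tax)
        assert s.f_hom_kegg == 0.0 and s.f_hom_eggnog == 0.0
        assert s.homogeneity_tag == "low_05"

    def test_high_in_one_database_is_ok(self):
        tax = {"M1": make_taxonomy("M1")}
        members = [
            make_protein("p1", "M1", kegg={"K1"}, eggnog={"d1"}),
            make_protein("p2", "M1", kegg={"K1"}, eggnog={"d2"}),
        ]
        assert score_pfc(1, members, tax).homogeneity_tag == "ok"


class TestRankSum:
    def test_complete_ties_give_p_one_flagged(self):
        p, degenerate = rank_sum_test(np.ones(5), np.ones(7))
        assert p == 1.0 and degenerate

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n1, n2 = rng.integers(2, 9, size=2)
            # tie-free samples exercise the exact path
            pool = rng.permutation(100)[: n1 + n2].astype(float)
            x, y = pool[:n1], pool[n1:]
            p, _ = rank_sum_test(x, y)
            assert p == pytest.approx(exact_ranksum_pvalue(x, y), abs=1e-12)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(11)
        x = rng.normal(10, 1, 200)
        y = rng.normal(0, 1, 200)
        p, _ = rank_sum_test(x, y)
        assert p < 0.05


class TestDarkAbundanceTest:
    def test_toy_medians(self):
        ab = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}, index=[1, 2, 3, 4, 5, 6]
        )
        res = dark_abundance_test(ab, dark_ids=[1, 2, 3])
        assert res.loc["s1", "dark_median"] == 2.0
        assert res.loc["s1", "other_median"] == 5.0

    def test_requires_two_per_group(self):
        ab = pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=[1, 2, 3])
        with pytest.raises(ValueError):
            dark_abundance_test(ab, dark_ids=[1])

    def test_strong_shift_is_significant_per_sample(self):
        rng = np.random.default_rng(8)
        n = 200
        dark = rng.normal(10, 1, size=(n, 3)) + 10
        other = rng.normal(10, 1, size=(n, 3))
        ab = pd.DataFrame(
            np.vstack([dark, other]),
            index=range(1, 2 * n + 1),
            columns=["s1", "s2", "s3"],
        )
        res = dark_abundance_test(ab, dark_ids=list(range(1, n + 1)))
        assert (res["p_value"] < 0.05).all()
        assert (res["dark_median"] > res["other_median"]).all()
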