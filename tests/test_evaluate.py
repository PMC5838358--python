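"""Recall, drug relevancy, agreement statistics, novel-term extraction."""

import numpy as np
import pytest

from streetlex import evaluate as ev
from streetlex.optimize import ExpertLexicon


class TestRecallVsExperts:
    def test_partial_match_percentage(self):
        gold = ExpertLexicon([f"g{i}" for i in range(32)])
        cands = [f"g{i}" for i in range(15)] + ["x", "y"]
        assert ev.recall_vs_experts(cands, gold) == 46.9

    def test_all_and_none(self):
        gold = ExpertLexicon(["a", "b"])
        assert ev.recall_vs_experts(["a", "b"], gold) == 100.0
        assert ev.recall_vs_experts(["x"], gold) == 0.0

    def test_variant_counts_as_match(self):
        gold = ExpertLexicon(["weed"], {"weed": {"weeed"}})
        assert ev.recall_vs_experts(["weeed"], gold) == 100.0

    def test_absent_terms_excluded_from_denominator(self):
        gold = ExpertLexicon(["a", "b", "c"], present_in_corpus={"c": False})
        assert ev.recall_vs_experts(["a"], gold) == 50.0

    def test_empty_gold_rejected(self):
        gold = ExpertLexicon(["a"], present_in_corpus={"a": False})
        with pytest.raises(ValueError):
            ev.recall_vs_experts(["a"], gold)


class TestDrugRelevancy:
    @pytest.mark.parametrize(
        "a1,a2,n,expected",
        [
            (180, 185, 200, 91.3),
            (91, 98, 112, 84.4),  # 84.375 rounds half-up
            (132, 170, 200, 75.5),
            (9, 12, 143, 7.3),
            (0, 0, 200, 0.0),
        ],
    )
    def test_reference_averages(self, a1, a2, n, expected):
        rec = ev.RelevancyRecord("t", n, a1, a2)
        assert ev.drug_relevancy(rec) == expected

    def test_invariant_to_annotator_swap(self):
        r1 = ev.RelevancyRecord("t", 200, 37, 54)
        r2 = ev.RelevancyRecord("t", 200, 54, 37)
        assert ev.drug_relevancy(r1) == ev.drug_relevancy(r2)

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            ev.RelevancyRecord("t", 0, 0, 0)


class TestSampleContexts:
    corpus = [["x", "term"], ["term"], ["y"], ["term", "z"]] + [["pad"]] * 5

    def test_fewer_occurrences_than_n_returns_all(self):
        got = ev.sample_contexts(self.corpus, "term", 200, seed=1)
        assert len(got) == 3

    def test_n_zero_empty(self):
        assert ev.sample_contexts(self.corpus, "term", 0, seed=1) == []

    def test_seeded_determinism_and_subsampling(self):
        a = ev.sample_contexts(self.corpus, "term", 2, seed=9)
        b = ev.sample_contexts(self.corpus, "term", 2, seed=9)
        assert a == b
        assert len(a) == 2
        assert all("term" in doc for doc in a)

    def test_absent_term_rejected(self):
        with pytest.raises(KeyError):
            ev.sample_contexts(self.corpus, "zzz", 5, seed=1)


class TestAgreement:
    def test_percent_agreement_matches_ratio(self):
        a = {f"t{i}": "marijuana" for i in range(200)}
        b = dict(a)
        for i in range(44):  # 156/200 agreements
            b[f"t{i}"] = "nondrug"
        assert ev.percent_agreement(a, b) == 78.0

    def test_identical_and_disjoint(self):
        a = {"x": "marijuana", "y": "nondrug"}
        assert ev.percent_agreement(a, dict(a)) == 100.0
        b = {"x": "nondrug", "y": "marijuana"}
        assert ev.percent_agreement(a, b) == 0.0

    def test_mismatched_term_sets_rejected(self):
        with pytest.raises(ValueError):
            ev.percent_agreement({"x": "marijuana"}, {"y": "marijuana"})


class TestCohenKappa:
    def test_identical_assignments_give_one(self):
        a = {"w": "marijuana", "x": "nondrug", "y": "other_drug", "z": "marijuana"}
        assert ev.cohen_kappa(a, dict(a)) == pytest.approx(1.0)

    def test_handwritten_confusion_matrix(self):
        # 2x2 confusion: [[20, 5], [10, 15]]; p_o = 35/50 = 0.7;
        # p_e = (25*30 + 25*20) / 2500 = 0.5; kappa = 0.4
        a, b = {}, {}
        idx = 0
        for (ca, cb), n in {("marijuana", "marijuana"): 20, ("marijuana", "nondrug"): 5,
                            ("nondrug", "marijuana"): 10, ("nondrug", "nondrug"): 15}.items():
            for _ in range(n):
                a[f"t{idx}"], b[f"t{idx}"] = ca, cb
                idx += 1
        assert ev.cohen_kappa(a, b) == pytest.approx(0.4)

    def test_independent_labelings_near_zero(self):
        rng = np.random.default_rng(0)
        cats = list(ev.CATEGORIES)
        terms = [f"t{i}" for i in range(100_000)]
        a = dict(zip(terms, rng.choice(cats, 100_000, p=[0.4, 0.3, 0.2, 0.1])))
        b = dict(zip(terms, rng.choice(cats, 100_000, p=[0.1, 0.2, 0.3, 0.4])))
        assert abs(ev.cohen_kappa(a, b)) < 0.01

    def test_kappa_never_exceeds_one(self):
        a = {"x": "marijuana", "y": "nondrug", "z": "nondrug"}
        b = {"x": "marijuana", "y": "marijuana", "z": "nondrug"}
        assert ev.cohen_kappa(a, b) <= 1.0

    def test_degenerate_marginals_rejected(self):
        a = {"x": "marijuana", "y": "marijuana"}
        with pytest.raises(ZeroDivisionError):
            ev.cohen_kappa(a, dict(a))


class TestAnnotatorCorrelation:
    def test_identical_annotators_give_one(self):
        recs = [ev.RelevancyRecord(f"t{i}", 200, h, h) for i, h in enumerate((10, 50, 120))]
        assert ev.annotator_correlation(recs) == pytest.approx(1.0)

    def test_handwritten_four_pairs(self):
        # percentages x = (10, 20, 30, 40), y = (15, 25, 20, 40):
        # sum dx*dy = 350, sum dx^2 = 500, sum dy^2 = 350,
        # r = 350 / sqrt(500 * 350) = sqrt(0.7) = 0.8366600265340756
        recs = [
            ev.RelevancyRecord("a", 100, 10, 15),
            ev.RelevancyRecord("b", 100, 20, 25),
            ev.RelevancyRecord("c", 100, 30, 20),
            ev.RelevancyRecord("d", 100, 40, 40),
        ]
        assert ev.annotator_correlation(recs) == pytest.approx(0.8366600265340756)

    def test_zero_variance_rejected(self):
        recs = [ev.RelevancyRecord(f"t{i}", 100, 10, i) for i in range(4)]
        with pytest.raises(ValueError):
            ev.annotator_correlation(recs)


class TestCategoryFrequencies:
    def test_counts_and_percentages(self):
        a = {"a": "marijuana", "b": "marijuana", "c": "nondrug", "d": "other_drug"}
        got = ev.category_frequencies(a)
        assert got["marijuana"] == (2, 50.0)
        assert got["process_or_paraphernalia"] == (0, 0.0)
        assert sum(n for n, _ in got.values()) == 4
        assert sum(p for _, p in got.values()) == pytest.approx(100.0, abs=0.2)

    def test_single_category(self):
        assert ev.category_frequencies({"a": "nondrug"})["nondrug"] == (1, 100.0)

    def test_empty_input_all_zero(self):
        got = ev.category_frequencies({})
        assert all(v == (0, 0.0) for v in got.values())

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            ev.category_frequencies({"a": "weird"})


class TestNovelTerms:
    def test_toy_partition_with_variant_pair(self):
        gold = ExpertLexicon(["kush"], {"kush": {"kushy"}})
        tech = ExpertLexicon(["thc"])
        report = ev.novel_terms(
            {"kush", "kushy", "thc", "gas", "gass", "piff"}, gold, tech,
            {"gas": {"gass"}},
        )
        assert report.expert_listed == {"kush", "kushy"}
        assert report.technical == {"thc"}
        assert report.novel_groups == [["gas", "gass"], ["piff"]]
        assert report.novel_count == 2

    def test_all_gold_gives_empty_novel_set(self):
        gold = ExpertLexicon(["a", "b"])
        report = ev.novel_terms({"a", "b"}, gold, ExpertLexicon([]))
        assert report.novel_count == 0

    def test_repetition_heuristic_groups_without_variant_file(self):
        gold, tech = ExpertLexicon(["zz"]), ExpertLexicon([])
        report = ev.novel_terms({"gas", "gass", "gasss"}, gold, tech)
        assert report.novel_groups == [["gas", "gass", "gasss"]]

    def test_packaged_fixture_recovers_30_groups(self):
        cats = ev.load_categorization()
        gold = ev.load_expert_lexicon()
        tech = ev.load_known_technical()
        marij = {t for t, c in cats.items() if c == "marijuana"}
        report = ev.novel_terms(marij, gold, tech, ev.load_variant_groups())
        assert report.novel_count == 30
        assert len(report.novel_terms_flat) == 36
        assert ["reefa", "reefer"] in report.novel_groups


def test_round_half_up_policy():
    assert ev.round_half_up(84.375) == 84.4
    assert ev.round_half_up(84.35) == 84.4
    assert ev.round_half_up(84.34) == 84.3
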