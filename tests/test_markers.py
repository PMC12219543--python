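"""Marker sets, set-level presence gaps, the threshold sweep and subgroups."""

import numpy as np
import pandas as pd
import pytest

import excessvocab as ev
from excessvocab.corpus import AbstractRecord, CorpusStore
from excessvocab.markers import (
    MarkerSet,
    SubgroupSpec,
    build_rare_set,
    combined_bound,
    common_set,
    covid_set,
    set_gap,
    set_presence_frequency,
    subgroup_gaps,
    sweep_threshold,
)
from excessvocab.synthetic import analytic_expected_gap


def _matrix_from_texts(texts, years):
    store = CorpusStore(records=[
        AbstractRecord(id=str(i), year=y, text=t)
        for i, (t, y) in enumerate(zip(texts, years))
    ])
    _v, matrix, _c = ev.build_matrix(store, min_doc_frac=0.0)
    return matrix


class TestSetPresence:
    def test_smoothed_presence_fraction(self):
        texts = ["aaaa zzzz"] * 3 + ["zzzz bbbb"] * 6
        matrix = _matrix_from_texts(texts, [2024] * 9)
        P = set_presence_frequency(matrix, MarkerSet("g", frozenset({"aaaa"})), 2024)
        assert P == pytest.approx(0.4)  # (3+1)/(9+1)

    def test_saturating_set(self):
        texts = ["aaaa cccc", "bbbb dddd"]
        matrix = _matrix_from_texts(texts, [2024] * 2)
        G = MarkerSet("all", frozenset({"aaaa", "bbbb"}))
        assert set_presence_frequency(matrix, G, 2024) == 1.0

    def test_absent_words_contribute_nothing(self):
        matrix = _matrix_from_texts(["aaaa"], [2024])
        G = MarkerSet("g", frozenset({"missingword"}))
        assert set_presence_frequency(matrix, G, 2024) == pytest.approx(0.5)

    def test_matches_scan_oracle_on_random_corpus(self, small_injection):
        matrix = small_injection["matrix"]
        store = small_injection["store"]
        rng = np.random.default_rng(0)
        words = frozenset(rng.choice(matrix.vocabulary.words, 5, replace=False))
        G = MarkerSet("g", words)
        year = 2024
        docs = [r for r in store if r.year == year]
        hits = sum(1 for r in docs if ev.tokenize(r.text) & words)
        expected = (hits + 1) / (len(docs) + 1)
        assert set_presence_frequency(matrix, G, year) == pytest.approx(expected)

    def test_presence_monotone_under_set_growth(self, small_injection):
        matrix = small_injection["matrix"]
        rng = np.random.default_rng(1)
        words = list(rng.choice(matrix.vocabulary.words, 6, replace=False))
        G = MarkerSet("g", frozenset(words[:5]))
        G_plus = MarkerSet("g+", frozenset(words))
        for year in range(2019, 2025):
            assert (set_presence_frequency(matrix, G_plus, year)
                    >= set_presence_frequency(matrix, G, year))


class TestSetGap:
    def test_singleton_reduces_to_word_level_delta(self, small_injection):
        matrix = small_injection["matrix"]
        counts = small_injection["counts"]
        word = "markaaa"
        gap = set_gap(matrix, MarkerSet("w", frozenset({word})), 2024)
        j = counts.vocabulary.index[word]
        freqs = counts.smoothed()
        p3 = freqs[counts.year_index(2021), j]
        p2 = freqs[counts.year_index(2022), j]
        p = freqs[counts.year_index(2024), j]
        q = ev.project_counterfactual(p3, p2)
        assert gap.P == pytest.approx(p)
        assert gap.Delta == pytest.approx(p - q)

    def test_stationary_set_has_near_zero_gap(self, small_injection):
        matrix = small_injection["matrix"]
        G = MarkerSet("bg", frozenset({"backaaa", "backaab", "backaac"}))
        gap = set_gap(matrix, G, 2024)
        assert abs(gap.Delta) < 0.02

    def test_injected_set_recovers_analytic_gap(self, small_injection):
        cfg = small_injection["config"]
        matrix = small_injection["matrix"]
        G = MarkerSet("markers", frozenset(cfg.marker_words()))
        gap = set_gap(matrix, G, 2024)
        expected = analytic_expected_gap(cfg, sorted(G.words), 2024)
        # 3 binomial standard errors at n = 2000 docs in the analysis year
        se = np.sqrt(0.8 * 0.2 / 2000)
        assert gap.Delta == pytest.approx(expected, abs=3 * 2 * se)
        assert gap.Delta <= cfg.lam + 3 * se

    def test_missing_years_fatal(self):
        matrix = _matrix_from_texts(["aaaa"] * 4, [2023] * 4)
        with pytest.raises(ValueError, match="missing"):
            set_gap(matrix, MarkerSet("g", frozenset({"aaaa"})), 2024)


class TestRareSetAndSweep:
    def _table(self):
        return pd.DataFrame({
            "word": ["rare", "mid", "edge", "bulk", "content", "notflagged"],
            "year": 2024,
            "p": [0.001, 0.019, 0.020, 0.3, 0.01, 0.01],
            "q": 0.001, "r": 2.0, "delta": 0.02,
            "eligible": True,
            "excess": [True, True, True, True, True, False],
            "category": ["style", "style", "style", "style", "content", "style"],
            "pos": "verb",
        })

    def test_strict_threshold_and_style_filter(self):
        G = build_rare_set(self._table(), T=0.02, year=2024)
        assert G.words == {"rare", "mid"}  # p < T strict; content/non-excess out

    def test_infinite_threshold_takes_all_style_excess(self):
        G = build_rare_set(self._table(), T=np.inf, year=2024)
        assert G.words == {"rare", "mid", "edge", "bulk"}

    def test_single_value_grid(self, small_injection):
        matrix = small_injection["matrix"]
        table = ev.detect_excess_words(
            small_injection["counts"], 2024,
            annotations=small_injection["annotations"])
        best_T, curve = sweep_threshold(table, matrix, 2024, T_grid=[0.5])
        assert best_T == 0.5 and len(curve) == 1

    def test_ties_break_toward_smallest_threshold(self, small_injection):
        matrix = small_injection["matrix"]
        table = ev.detect_excess_words(
            small_injection["counts"], 2024,
            annotations=small_injection["annotations"])
        # both thresholds exceed every marker frequency -> identical sets
        best_T, curve = sweep_threshold(table, matrix, 2024, T_grid=[0.4, 0.5])
        assert best_T == 0.4
        assert curve["Delta"].nunique() == 1

    def test_curve_rises_to_plateau_past_marker_frequencies(self, small_injection):
        matrix = small_injection["matrix"]
        table = ev.detect_excess_words(
            small_injection["counts"], 2024,
            annotations=small_injection["annotations"])
        best_T, curve = sweep_threshold(table, matrix, 2024)
        low = curve[curve["T"] < 1e-3]["Delta"]
        high = curve[curve["T"] > 0.1]["Delta"]
        assert high.iloc[0] > low.max() + 0.05
        assert high.nunique() == 1  # plateau: same set beyond the largest marker p

    def test_adding_common_word_can_dilute_the_gap(self):
        # "omnip" appears in 90/100 docs every year; the 30 new "rarely"
        # docs in 2024 are all among them, so the union gains nothing.
        texts, years = [], []
        for year in (2021, 2022, 2023, 2024):
            for i in range(100):
                toks = []
                if i < 90:
                    toks.append("omnip")
                if year == 2024 and i < 30:
                    toks.append("rarely")
                texts.append(" ".join(toks) or "zzzz")
                years.append(year)
        matrix = _matrix_from_texts(texts, years)
        d_rare = set_gap(matrix, MarkerSet("r", frozenset({"rarely"})), 2024).Delta
        d_union = set_gap(
            matrix, MarkerSet("ru", frozenset({"rarely", "omnip"})), 2024).Delta
        assert d_union < d_rare


class TestBuiltinSetsAndBound:
    def test_common_set_membership(self):
        G = common_set()
        assert len(G) == 10
        assert G.words == {
            "across", "additionally", "comprehensive", "crucial", "enhancing",
            "exhibited", "insights", "notably", "particularly", "within",
        }
        assert "delves" not in G.words

    def test_covid_reference_set(self):
        assert covid_set().words == {"covid", "pandemic", "coronavirus", "sars"}

    @pytest.mark.parametrize(("a", "b", "expected"), [
        (0.136, 0.134, 0.135),
        (0.2, 0.2, 0.2),
        (0.0, 0.2, 0.1),
    ])
    def test_combined_bound_is_the_mean(self, a, b, expected):
        assert combined_bound(a, b) == pytest.approx(expected)


class TestSubgroups:
    def test_undersized_year_excludes_subgroup_with_reason(self):
        texts, years, countries = [], [], []
        for year in (2021, 2022, 2023, 2024):
            for c, n in (("aaland", 299 if year == 2022 else 300), ("bbland", 300)):
                for _ in range(n):
                    texts.append("wordword")
                    years.append(year)
                    countries.append(c)
        store = CorpusStore(records=[
            AbstractRecord(id=str(i), year=y, text=t, country=c)
            for i, (t, y, c) in enumerate(zip(texts, years, countries))
        ])
        _v, matrix, _c = ev.build_matrix(store, 0.0)
        spec = SubgroupSpec(key="country", min_docs_per_year=300,
                            eligibility_years=(2021, 2023))
        res, excluded = subgroup_gaps(
            matrix, "country", [MarkerSet("g", frozenset({"wordword"}))], spec, 2024)
        assert set(res["subgroup"]) == {"bbland"}
        assert list(excluded["subgroup"]) == ["aaland"]
        assert "299" in excluded["reason"].iloc[0]

    def test_adoption_rate_ordering_recovered(self, country_injection):
        cfg = country_injection["config"]
        matrix = country_injection["matrix"]
        G = MarkerSet("markers", frozenset(cfg.marker_words()))
        spec = SubgroupSpec(key="country", min_docs_per_year=300,
                            eligibility_years=(2019, 2023))
        res, excl = subgroup_gaps(matrix, "country", [G], spec, 2024)
        assert excl.empty
        d = dict(zip(res["subgroup"], res["Delta"]))
        assert d["aaland"] < d["bbland"]
        for name in ("aaland", "bbland"):
            expected = analytic_expected_gap(
                cfg, cfg.marker_words(), 2024, lam=cfg.country_lambdas[name])
            se = np.sqrt(0.8 * 0.2 / 2000)
            assert d[name] == pytest.approx(expected, abs=3 * 2 * se)

    def test_pooling_equal_sized_groups_averages_their_gaps(self, country_injection):
        cfg = country_injection["config"]
        matrix = country_injection["matrix"]
        G = MarkerSet("markers", frozenset(cfg.marker_words()))
        spec_sep = SubgroupSpec(key="country", eligibility_years=(2019, 2023))
        sep, _ = subgroup_gaps(matrix, "country", [G], spec_sep, 2024)
        spec_pool = SubgroupSpec(key="country", eligibility_years=(2019, 2023),
                                 groups={"pooled": "aaland|bbland"})
        pooled, _ = subgroup_gaps(matrix, "country", [G], spec_pool, 2024)
        mean_sep = sep["Delta"].mean()
        assert pooled["Delta"].iloc[0] == pytest.approx(mean_sep, abs=0.02)

    def test_unknown_key_is_fatal(self, small_injection):
        with pytest.raises(KeyError):
            subgroup_gaps(small_injection["matrix"], "nonsense", [common_set()],
                          SubgroupSpec(key="nonsense"), 2024)
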