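"""Path enumeration, noisy views, weakest-link comparison, optimal paths."""

import numpy as np
import pytest
from scipy.stats import norm

from l2lp import (
    AcousticInput,
    GrammarEvaluator,
    MinimalPair,
    NoiseModel,
    build_l1_grammar,
    compare_paths,
    draw_noisy_view,
    enumerate_paths,
    evaluate_optimal_path,
    full_copy_to_l2,
    perceive_phonetic,
)

from conftest import DUTCH, brute_force_winners, random_l2_grammar


class TestEnumerate:
    def test_full_candidate_space_is_18_paths(self, l2_grammar):
        paths = enumerate_paths(l2_grammar, AcousticInput(4.0, "chica-checa"))
        assert len(paths) == 18
        assert len({(p.phonetic, p.phonemic, p.meaning) for p in paths}) == 18

    def test_meaning_restriction_gives_9_paths(self, l2_grammar):
        paths = enumerate_paths(l2_grammar, AcousticInput(4.0, "chica-checa"), "girl")
        assert len(paths) == 9
        assert all(p.meaning == "girl" for p in paths)

    def test_degenerate_network_single_path(self):
        l1 = build_l1_grammar(("i",))
        pair = MinimalPair("p", "a", "b", "ma", "mb")
        g = full_copy_to_l2(l1, (pair,))
        assert len(enumerate_paths(g, AcousticInput(4.0, "p"))) == 2
        assert len(enumerate_paths(g, AcousticInput(4.0, "p"), "ma")) == 1

    def test_unknown_carrier_and_off_grid_bin(self, l2_grammar):
        with pytest.raises(KeyError):
            enumerate_paths(l2_grammar, AcousticInput(4.0, "nope"))
        with pytest.raises(KeyError):
            enumerate_paths(l2_grammar, AcousticInput(4.07, "chica-checa"))


class TestNoisyView:
    def test_zero_noise_view_equals_stored_values(self, l2_grammar, rng):
        view = draw_noisy_view(l2_grammar, NoiseModel(0.0), rng)
        assert np.array_equal(view.perception, l2_grammar.perception)
        assert np.array_equal(view.lexical_table, l2_grammar.lexical_table)

    def test_noise_distribution_moments(self, l2_grammar, rng):
        conn = ("perception", 4.0, "ɪ")
        draws = np.array([
            draw_noisy_view(l2_grammar, NoiseModel(2.0), rng).value(conn)
            for _ in range(10_000)
        ])
        assert abs(draws.mean() - l2_grammar.value(conn)) < 0.1
        assert abs(draws.std() - 2.0) < 0.1

    def test_shared_connection_has_single_noisy_value(self, l2_grammar, rng):
        view = draw_noisy_view(l2_grammar, NoiseModel(2.0), rng)
        p1, p2 = enumerate_paths(l2_grammar, AcousticInput(4.0, "chica-checa"))[:2]
        shared = set(p1.connections) & set(p2.connections)
        assert shared
        for conn in shared:
            assert view.value(conn) == view.value(conn)

    def test_grammar_not_mutated_by_drawing(self, l2_grammar, rng):
        before = l2_grammar.perception.copy()
        draw_noisy_view(l2_grammar, NoiseModel(2.0), rng)
        assert np.array_equal(l2_grammar.perception, before)


def _fixed_view(grammar, assignments):
    """Zero-noise view with chosen connection values poked into a copy."""
    g = grammar.copy()
    for conn, value in assignments.items():
        table, idx = g._locate(conn)
        table[idx] = value
    return g, draw_noisy_view(g, NoiseModel(0.0))


class TestComparePaths:
    def test_maximin_on_three_element_profiles(self, l2_grammar):
        g, view = _fixed_view(l2_grammar, {
            ("perception", 4.0, "i"): 95, ("phonemic", "i", "i"): 95,
            ("lexical", "chica-checa", "i", "girl"): 100,
            ("perception", 4.0, "ɪ"): 95, ("phonemic", "ɪ", "ɪ"): 105,
            ("lexical", "chica-checa", "ɪ", "girl"): 90,
        })
        paths = enumerate_paths(g, AcousticInput(4.0, "chica-checa"))
        p1 = next(p for p in paths if (p.phonetic, p.phonemic, p.meaning) == ("i", "i", "girl"))
        p2 = next(p for p in paths if (p.phonetic, p.phonemic, p.meaning) == ("ɪ", "ɪ", "girl"))
        assert compare_paths(p1, p2, view) == "p1_wins"  # worst 100 < worst 105

    def test_lexicographic_tiebreak_on_next_worst(self, l2_grammar):
        # both paths share the perception link (the common worst); the
        # second-worst value decides
        g, view = _fixed_view(l2_grammar, {
            ("perception", 4.0, "i"): 110,
            ("phonemic", "i", "i"): 98, ("lexical", "chica-checa", "i", "girl"): 90,
            ("phonemic", "i", "ɪ"): 101, ("lexical", "chica-checa", "ɪ", "girl"): 90,
        })
        paths = enumerate_paths(g, AcousticInput(4.0, "chica-checa"))
        p1 = next(p for p in paths if (p.phonetic, p.phonemic, p.meaning) == ("i", "i", "girl"))
        p2 = next(p for p in paths if (p.phonetic, p.phonemic, p.meaning) == ("i", "ɪ", "girl"))
        assert compare_paths(p1, p2, view) == "p1_wins"

    def test_tie_on_identical_profiles(self, l2_grammar):
        view = draw_noisy_view(l2_grammar, NoiseModel(0.0))
        paths = enumerate_paths(l2_grammar, AcousticInput(4.0, "chica-checa"))
        # untrained grammar: faithful i-path to either meaning has an
        # identical profile
        p1 = next(p for p in paths if (p.phonetic, p.phonemic, p.meaning) == ("i", "i", "girl"))
        p2 = next(p for p in paths if (p.phonetic, p.phonemic, p.meaning) == ("i", "i", "czech.f"))
        assert compare_paths(p1, p2, view) == "tie"


def _divergence_grammar(l1_grammar, small_pairs, mode):
    """Perception prefers /i/ by 1 unit, but every recognition link on the
    /i/ side is weak (120) while all /ɪ/-side recognition links are <= 95."""
    g = full_copy_to_l2(l1_grammar, small_pairs, mode=mode)
    g.perception[:] = 150.0
    b = g.bin_index(4.0)
    g.perception[b, :] = [100.0, 101.0, 150.0]
    g.phonemic_table[:] = 95.0
    g.phonemic_table[0, :] = 120.0  # /i/ -> any phonemic form
    g.lexical_table[:] = 95.0
    return g


class TestSequentialInteractiveDivergence:
    def test_sequential_perception_stratum_screens_lexicon(self, l1_grammar, small_pairs):
        g = _divergence_grammar(l1_grammar, small_pairs, "sequential")
        win = evaluate_optimal_path(g, AcousticInput(4.0, "chica-checa"), NoiseModel(0.0),
                                    np.random.default_rng(0))
        assert win.phonetic == "i"

    def test_interactive_lexicon_overrides_perception(self, l1_grammar, small_pairs):
        g = _divergence_grammar(l1_grammar, small_pairs, "interactive")
        win = evaluate_optimal_path(g, AcousticInput(4.0, "chica-checa"), NoiseModel(0.0),
                                    np.random.default_rng(0))
        assert win.phonetic == "ɪ"  # profile worst 101 < the /i/-side 120


class TestOptimalPath:
    def test_dominant_path_always_wins_without_noise(self, l2_grammar):
        g, _ = _fixed_view(l2_grammar, {})
        b = g.bin_index(3.0)
        g.perception[b, 0] = 90.0
        g.phonemic_table[0, 0] = 90.0
        g.lexical_table[0, 0, 0] = 90.0
        rng = np.random.default_rng(1)
        for _ in range(20):
            win = evaluate_optimal_path(g, AcousticInput(3.0, "chica-checa"),
                                        NoiseModel(0.0), rng)
            assert (win.phonetic, win.phonemic, win.meaning) == ("i", "i", "girl")

    def test_matches_brute_force_oracle_on_shared_view(self, rng):
        for mode in ("sequential", "interactive"):
            for _ in range(150):
                g = random_l2_grammar(rng, mode)
                f1 = float(g.bins[rng.integers(61)])
                inp = AcousticInput(f1, g.pairs[rng.integers(len(g.pairs))].pair_id)
                view = draw_noisy_view(g, NoiseModel(2.0), rng)
                win = evaluate_optimal_path(g, inp, NoiseModel(2.0), rng, view=view)
                paths, winners = brute_force_winners(g, inp, view)
                keys = [(paths[k].phonetic, paths[k].phonemic, paths[k].meaning) for k in winners]
                assert (win.phonetic, win.phonemic, win.meaning) in keys
                assert len(winners) == 1  # continuous noise: a.s. unique

    def test_fast_engine_agrees_with_reference_on_shared_view(self, rng):
        for mode in ("sequential", "interactive"):
            for _ in range(150):
                g = random_l2_grammar(rng, mode)
                b = int(rng.integers(61))
                pr = int(rng.integers(len(g.pairs)))
                view = draw_noisy_view(g, NoiseModel(2.0), rng)
                ev = GrammarEvaluator(g, 2.0)
                noisy = ev.noisy_from_view(view, b, pr)
                i, j, m = ev.evaluate(b, pr, rng, noisy=noisy)
                inp = AcousticInput(float(g.bins[b]), g.pairs[pr].pair_id)
                win = evaluate_optimal_path(g, inp, NoiseModel(2.0), rng, view=view)
                assert (g.phonetic[i], g.phonemic[j], g.pairs[pr].meanings[m]) == (
                    win.phonetic, win.phonemic, win.meaning)

    def test_uniform_tiebreak_between_identical_candidates(self):
        l1 = build_l1_grammar(("i",))
        pair = MinimalPair("p", "a", "b", "ma", "mb")
        g = full_copy_to_l2(l1, (pair,))  # two fully symmetric meaning paths
        rng = np.random.default_rng(3)
        wins = sum(
            evaluate_optimal_path(g, AcousticInput(4.0, "p"), NoiseModel(0.0), rng).meaning == "ma"
            for _ in range(10_000)
        )
        assert abs(wins / 10_000 - 0.5) < 0.02

    def test_sequential_screening_property(self, rng):
        # in sequential mode the winning phonetic is fixed by the perception
        # draw alone: randomizing the recognition tables never changes it
        g = random_l2_grammar(rng, "sequential")
        b, pr = 30, 0
        view = draw_noisy_view(g, NoiseModel(2.0), rng)
        expected = int(np.argmin(view.perception[b]))
        ev = GrammarEvaluator(g, 2.0)
        for _ in range(25):
            view.phonemic_table[:] = 100 + 20 * rng.standard_normal(view.phonemic_table.shape)
            view.lexical_table[:] = 100 + 20 * rng.standard_normal(view.lexical_table.shape)
            i, _, _ = ev.evaluate(b, pr, rng, noisy=ev.noisy_from_view(view, b, pr))
            assert i == expected


class TestPerceivePhonetic:
    def test_argmin_without_noise(self, l1_grammar):
        b = l1_grammar.bin_index(3.0)
        l1_grammar.perception[b] = [95.0, 100.0, 100.0]
        assert perceive_phonetic(l1_grammar, 3.0, NoiseModel(0.0)) == "i"

    def test_choice_probability_matches_gaussian_closed_form(self, rng):
        # two categories 2 apart under sd-2 noise: P = Phi(2 / (2*sqrt(2)))
        g = build_l1_grammar(("i", "ɪ"))
        b = g.bin_index(4.0)
        g.perception[b] = [99.0, 101.0]
        n = 20_000
        wins = sum(perceive_phonetic(g, 4.0, NoiseModel(2.0), rng) == "i" for _ in range(n))
        expected = norm.cdf(2.0 / (2.0 * np.sqrt(2.0)))
        assert abs(wins / n - expected) < 0.01

    def test_symmetry_with_equal_values(self, l1_grammar, rng):
        counts = {v: 0 for v in DUTCH}
        for _ in range(12_000):
            counts[perceive_phonetic(l1_grammar, 5.0, NoiseModel(2.0), rng)] += 1
        for v in DUTCH:
            assert abs(counts[v] / 12_000 - 1 / 3) < 0.02
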