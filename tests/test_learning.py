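"""Plasticity schedule, error-driven updates, interpretive parsing, training."""

import numpy as np
import pytest

from l2lp import (
    AcousticInput,
    ConfigurationError,
    NoiseModel,
    PlasticitySchedule,
    Token,
    build_l1_grammar,
    draw_noisy_view,
    enumerate_paths,
    full_copy_to_l2,
    interpretive_parse,
    plasticity_at,
    train_learner,
    update_on_error,
)

from conftest import brute_force_winners


class TestPlasticity:
    @pytest.mark.parametrize(
        "step, expected",
        [(0, 0.1), (9_999, 0.1), (10_000, 0.07), (25_000, 0.049), (40_000, 0.1 * 0.7**4)],
    )
    def test_decay_values(self, step, expected):
        assert plasticity_at(PlasticitySchedule(), step) == pytest.approx(expected, rel=1e-12)

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            plasticity_at(PlasticitySchedule(), -1)

    def test_non_increasing(self):
        s = PlasticitySchedule()
        vals = [s.at(k) for k in range(0, 60_000, 5_000)]
        assert all(a >= b > 0 for a, b in zip(vals, vals[1:]))


class TestTokens:
    def test_phase_invariants(self):
        with pytest.raises(ConfigurationError):
            Token("L1", 3.0, "i", carrier="chica-checa")
        with pytest.raises(ConfigurationError):
            Token("L2", 3.0, "girl")
        with pytest.raises(ConfigurationError):
            Token("L3", 3.0, "x")


class TestUpdateOnError:
    def _paths(self, grammar, phonetics, phonemics, meanings):
        paths = enumerate_paths(grammar, AcousticInput(4.0, "chica-checa"))
        a = next(p for p in paths
                 if (p.phonetic, p.phonemic, p.meaning) == (phonetics[0], phonemics[0], meanings[0]))
        b = next(p for p in paths
                 if (p.phonetic, p.phonemic, p.meaning) == (phonetics[1], phonemics[1], meanings[1]))
        return a, b

    def test_shared_perception_link_nets_exactly_zero(self, l2_grammar):
        wrong, target = self._paths(l2_grammar, ("i", "i"), ("i", "ɪ"), ("czech.f", "girl"))
        before = {c: l2_grammar.value(c) for c in set(wrong.connections) | set(target.connections)}
        update_on_error(l2_grammar, wrong, target, 0.1)
        shared = ("perception", 4.0, "i")
        assert l2_grammar.value(shared) == before[shared]  # bit-exact
        assert l2_grammar.value(("phonemic", "i", "i")) == before[("phonemic", "i", "i")] + 0.1
        assert l2_grammar.value(("phonemic", "i", "ɪ")) == before[("phonemic", "i", "ɪ")] - 0.1
        assert l2_grammar.value(("lexical", "chica-checa", "i", "czech.f")) == 100.1
        assert l2_grammar.value(("lexical", "chica-checa", "ɪ", "girl")) == 99.9

    def test_identical_paths_leave_grammar_unchanged(self, l2_grammar):
        wrong, _ = self._paths(l2_grammar, ("i", "i"), ("i", "i"), ("girl", "czech.f"))
        perc = l2_grammar.perception.copy()
        phon = l2_grammar.phonemic_table.copy()
        lex = l2_grammar.lexical_table.copy()
        update_on_error(l2_grammar, wrong, wrong, 0.1)
        assert np.array_equal(l2_grammar.perception, perc)
        assert np.array_equal(l2_grammar.phonemic_table, phon)
        assert np.array_equal(l2_grammar.lexical_table, lex)

    def test_total_change_is_conserved(self, l2_grammar):
        wrong, target = self._paths(l2_grammar, ("i", "ɛ"), ("i", "ɛ"), ("czech.f", "girl"))
        tables = lambda g: np.concatenate(
            [g.perception.ravel(), g.phonemic_table.ravel(), g.lexical_table.ravel()]
        )
        before = tables(l2_grammar).sum()
        update_on_error(l2_grammar, wrong, target, 0.1)
        assert tables(l2_grammar).sum() == pytest.approx(before, abs=1e-9)


class TestInterpretiveParse:
    def test_zero_noise_parse_is_deterministic_best_target_path(self, l2_grammar):
        l2_grammar.phonemic_table[:] = 105.0
        l2_grammar.phonemic_table[2, 2] = 90.0  # /ɛ/ -> |ɛ| strong
        l2_grammar.lexical_table[:] = 100.0
        parse = interpretive_parse(l2_grammar, AcousticInput(4.0, "chica-checa"),
                                   "girl", NoiseModel(0.0), np.random.default_rng(0))
        assert parse.meaning == "girl"
        assert (parse.phonetic, parse.phonemic) == ("ɛ", "ɛ")

    def test_parse_equals_brute_force_on_fresh_view(self, l2_grammar, rng):
        view = draw_noisy_view(l2_grammar, NoiseModel(2.0), rng)
        parse = interpretive_parse(l2_grammar, AcousticInput(4.0, "chica-checa"),
                                   "girl", NoiseModel(2.0), rng, view=view)
        paths, winners = brute_force_winners(
            l2_grammar, AcousticInput(4.0, "chica-checa"), view, restrict_to_meaning="girl")
        assert len(paths) == 9
        keys = [(paths[k].phonetic, paths[k].phonemic) for k in winners]
        assert (parse.phonetic, parse.phonemic) in keys


def _toy_stream(n, q, rng, bin_a=3.0, bin_b=5.0):
    """Two-bin stream: bin_a is category X with probability q, bin_b always Y."""
    tokens = []
    for _ in range(n):
        if rng.random() < 0.5:
            cat = "X" if rng.random() < q else "Y"
            tokens.append(Token("L1", bin_a, cat, category=cat))
        else:
            tokens.append(Token("L1", bin_b, "Y", category="Y"))
    return tokens


class TestTrainLearner:
    def test_error_free_stream_leaves_grammar_unchanged(self):
        g = build_l1_grammar(("X", "Y"))
        g.perception[:, 0] = 90.0
        g.perception[:, 1] = 110.0  # X always wins at sd 0
        tokens = [Token("L1", 3.0, "X", category="X")] * 500
        before = g.perception.copy()
        _, records = train_learner(g, tokens, NoiseModel(0.0), PlasticitySchedule(),
                                   seed=0, trace=True)
        assert np.array_equal(g.perception, before)
        assert not any(r.error for r in records)

    def test_two_bin_toy_problem_converges(self, rng):
        g = build_l1_grammar(("X", "Y"))
        stream = _toy_stream(5_000, 1.0, rng)
        train_learner(g, stream, NoiseModel(2.0), PlasticitySchedule(), seed=1)
        # error rate on the same stream after training
        from l2lp import recognition_rate

        assert recognition_rate(g, stream, 2.0, np.random.default_rng(2)) > 0.95

    @pytest.mark.parametrize("q", [0.5, 0.8])
    def test_probability_matching_equilibrium(self, q, rng):
        # per-bin choice probabilities converge to the input proportions
        g = build_l1_grammar(("X", "Y"))
        stream = _toy_stream(30_000, q, rng)
        train_learner(g, stream, NoiseModel(2.0), PlasticitySchedule(), seed=3)
        from l2lp import GrammarEvaluator

        ev = GrammarEvaluator(g, 2.0)
        b = g.bin_index(3.0)
        prng = np.random.default_rng(4)
        freq = np.mean([ev.evaluate_l1(b, prng) == 0 for _ in range(20_000)])
        assert abs(freq - q) < 0.07

    def test_phase_mismatch_rejected(self, l1_grammar, l2_grammar):
        l2_tokens = [Token("L2", 3.0, "girl", carrier="chica-checa")]
        with pytest.raises(ConfigurationError):
            train_learner(l1_grammar, l2_tokens, NoiseModel(2.0), PlasticitySchedule(), seed=0)
        l1_tokens = [Token("L1", 3.0, "i", category="i")]
        with pytest.raises(ConfigurationError):
            train_learner(l2_grammar, l1_tokens, NoiseModel(2.0), PlasticitySchedule(), seed=0)

    def test_flipped_update_sign_prevents_learning(self, rng):
        g = build_l1_grammar(("X", "Y"))
        stream = _toy_stream(3_000, 1.0, rng)
        train_learner(g, stream, NoiseModel(2.0), PlasticitySchedule(), seed=5,
                      update_sign=-1.0)
        from l2lp import recognition_rate

        assert recognition_rate(g, stream, 2.0, np.random.default_rng(6)) < 0.8

    def test_l2_training_reduces_errors_and_probe_sees_checkpoints(self, l1_grammar, small_pairs):
        from l2lp.corpus import spanish_config, generate_corpus

        g = full_copy_to_l2(l1_grammar, small_pairs, mode="interactive")
        cfg = spanish_config(n_tokens=400, pairs=small_pairs)
        tokens = generate_corpus(cfg, np.random.default_rng(7))
        stream = tokens * 30  # 12,000 steps
        seen = []
        _, records = train_learner(
            g, stream, NoiseModel(2.0), PlasticitySchedule(),
            checkpoints=(0, 12_000), probe=lambda s, _g: seen.append(s),
            seed=8, trace=True,
        )
        assert seen == [0, 12_000]
        early = np.mean([r.error for r in records[:1000]])
        late = np.mean([r.error for r in records[-1000:]])
        assert late < early - 0.1

    def test_trace_export(self, tmp_path, rng):
        import pandas as pd

        from l2lp import write_trace

        g = build_l1_grammar(("X", "Y"))
        stream = _toy_stream(200, 0.7, rng)
        _, records = train_learner(g, stream, NoiseModel(2.0), PlasticitySchedule(),
                                   seed=9, trace=True)
        write_trace(records, tmp_path / "trace.tsv")
        df = pd.read_csv(tmp_path / "trace.tsv", sep="\t")
        assert list(df.columns) == ["step", "error", "winner_phonetic",
                                    "winner_meaning", "plasticity"]
        assert len(df) == 200
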