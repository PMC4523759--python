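import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from l2lp import (
    AcousticInput,
    MinimalPair,
    NoiseModel,
    build_l1_grammar,
    compare_paths,
    default_lexicon,
    enumerate_paths,
    full_copy_to_l2,
)

DUTCH = ("i", "ɪ", "ɛ")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_pairs():
    return (
        MinimalPair("chica-checa", "tʃika", "tʃeka", "girl", "czech.f"),
        MinimalPair("pair_01", "p1i", "p1e", "p1.i", "p1.e"),
        MinimalPair("pair_02", "p2i", "p2e", "p2.i", "p2.e"),
    )


@pytest.fixture
def l1_grammar():
    return build_l1_grammar(DUTCH)


@pytest.fixture
def l2_grammar(l1_grammar, small_pairs):
    return full_copy_to_l2(l1_grammar, small_pairs, mode="sequential")


def random_l2_grammar(rng, mode, n_pairs=2, spread=15.0):
    """A full grammar with randomized ranking values, for property tests."""
    pairs = default_lexicon(n_pairs - 1)
    l1 = build_l1_grammar(DUTCH)
    l1.perception[:] = 100.0 + spread * rng.standard_normal(l1.perception.shape)
    g = full_copy_to_l2(l1, pairs, mode=mode)
    g.phonemic_table[:] = 100.0 + spread * rng.standard_normal(g.phonemic_table.shape)
    g.lexical_table[:] = 100.0 + spread * rng.standard_normal(g.lexical_table.shape)
    return g


def brute_force_winners(grammar, inp, view, restrict_to_meaning=None):
    """Independent oracle: exhaustive pairwise weakest-link tournament.

    Returns the set of path indices that lose to no other candidate.
    """
    paths = enumerate_paths(grammar, inp, restrict_to_meaning)
    winners = []
    for k, p in enumerate(paths):
        beaten = any(
            compare_paths(p, q, view) == "p2_wins" for j, q in enumerate(paths) if j != k
        )
        if not beaten:
            winners.append(k)
    return paths, winners
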