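"""Stochastic evaluation of candidate perception/recognition paths.

An incoming token activates every path from its acoustic bin up to the
lexicon (3 phonetic × 3 phonemic × 2 meanings = 18 paths in the standard
network).  Before each evaluation event every connection's ranking value is
distorted by a fresh zero-mean Gaussian draw (stochastic evaluation); a
connection shared by several paths keeps a single noisy value within the
event.

A path is as strong as its weakest link: candidates are compared by their
worst (most dominant) violation first, then lexicographically down the
sorted violation profile — never by summing strengths.  Connections are
ordered first by stratum and then by noisy ranking value, which is what
makes the sequential/interactive contrast: with perception in a higher
stratum the phonetic decision screens off all lexical evidence, while in a
single stratum lexical connections can outrank perception ones and feed
back into the phonetic outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grammar import AcousticInput, Grammar

__all__ = [
    "NoiseModel",
    "Path",
    "NoisyGrammarView",
    "enumerate_paths",
    "draw_noisy_view",
    "compare_paths",
    "evaluate_optimal_path",
    "perceive_phonetic",
    "GrammarEvaluator",
]


@dataclass(frozen=True)
class NoiseModel:
    """Zero-mean Gaussian evaluation noise with standard deviation ``sd``."""

    sd: float = 2.0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass(frozen=True)
class Path:
    """One candidate route [acoustic] -> /phonetic/ -> |phonemic| -> <lexical>.

    ``connections`` holds the traversed connection keys (one key for a
    perception-only L1 path, three for a full L2 path).
    """

    f1_bin: float
    phonetic: str
    phonemic: str | None = None
    meaning: str | None = None
    carrier: str | None = None
    connections: tuple = ()


class NoisyGrammarView:
    """One noisy value per connection, frozen for one evaluation event."""

    def __init__(self, grammar: Grammar, perception, phonemic_table=None, lexical_table=None):
        self.grammar = grammar
        self.perception = perception
        self.phonemic_table = phonemic_table
        self.lexical_table = lexical_table
        self._tables = {
            "perception": perception,
            "phonemic": phonemic_table,
            "lexical": lexical_table,
        }

    def value(self, conn) -> float:
        """Noisy ranking value of a connection key."""
        _, idx = self.grammar._locate(conn)
        return float(self._tables[conn[0]][idx])

    def stratum(self, conn) -> int:
        return self.grammar.strata[conn[0]]


def draw_noisy_view(grammar: Grammar, noise: NoiseModel, rng=None) -> NoisyGrammarView:
    """Distort every connection of the grammar with iid Gaussian noise.

    The grammar's stored values are untouched; the returned view carries a
    single noisy value per connection.
    """
    rng = np.random.default_rng() if rng is None else rng
    perc = grammar.perception + noise.sd * rng.standard_normal(grammar.perception.shape)
    phon = lex = None
    if grammar.phonemic_table is not None:
        phon = grammar.phonemic_table + noise.sd * rng.standard_normal(grammar.phonemic_table.shape)
    if grammar.lexical_table is not None:
        lex = grammar.lexical_table + noise.sd * rng.standard_normal(grammar.lexical_table.shape)
    return NoisyGrammarView(grammar, perc, phon, lex)


def enumerate_paths(grammar: Grammar, inp: AcousticInput, restrict_to_meaning: str | None = None):
    """All candidate paths for an acoustic input.

    For a full grammar this is every phonetic × phonemic × meaning
    combination within the carrier pair's subnetwork (18 in the standard
    network; 9 when restricted to one target meaning).  For a perception-only
    grammar, one single-connection path per phonetic vowel.
    """
    f1 = float(inp.f1_bin)
    grammar.bin_index(f1)  # validates the bin
    if not grammar.is_lexical:
        return [
            Path(f1, pv, connections=(("perception", f1, pv),))
            for pv in grammar.phonetic
        ]
    if inp.carrier is None:
        raise KeyError("a full grammar requires a carrier pair on the input")
    pair = grammar.pair(inp.carrier)
    paths = []
    for pv in grammar.phonetic:
        for qv in grammar.phonemic:
            for meaning in pair.meanings:
                if restrict_to_meaning is not None and meaning != restrict_to_meaning:
                    continue
                paths.append(
                    Path(
                        f1, pv, qv, meaning, pair.pair_id,
                        connections=(
                            ("perception", f1, pv),
                            ("phonemic", pv, qv),
                            ("lexical", pair.pair_id, qv, meaning),
                        ),
                    )
                )
    return paths


def _profile(path: Path, view: NoisyGrammarView):
    """(stratum, noisy value) pairs sorted with the worst violation first."""
    return tuple(sorted(((view.stratum(c), view.value(c)) for c in path.connections), reverse=True))


def compare_paths(p1: Path, p2: Path, view: NoisyGrammarView) -> str:
    """Weakest-link comparison of two candidate paths under one noisy view.

    Violation profiles are compared position-wise from the most dominant
    connection down; at the first differing position the path holding the
    dominating (worse) connection loses.  Returns ``"p1_wins"``,
    ``"p2_wins"`` or ``"tie"``.
    """
    a, b = _profile(p1, view), _profile(p2, view)
    if a == b:
        return "tie"
    return "p1_wins" if a < b else "p2_wins"


def evaluate_optimal_path(
    grammar: Grammar,
    inp: AcousticInput,
    noise: NoiseModel,
    rng=None,
    restrict_to_meaning: str | None = None,
    view: NoisyGrammarView | None = None,
) -> Path:
    """Draw one noisy view and return the optimal path for an input.

    The winner is the unique path whose sorted violation profile is minimal;
    exact profile ties (a measure-zero event under continuous noise) are
    broken uniformly at random.  A pre-drawn ``view`` may be supplied to
    re-evaluate on a fixed noise draw.
    """
    paths = enumerate_paths(grammar, inp, restrict_to_meaning)
    if view is None:
        view = draw_noisy_view(grammar, noise, rng)
    profiles = [_profile(p, view) for p in paths]
    best = min(profiles)
    winners = [k for k, pr in enumerate(profiles) if pr == best]
    if len(winners) == 1:
        return paths[winners[0]]
    rng = np.random.default_rng() if rng is None else rng
    return paths[winners[int(rng.integers(len(winners)))]]


def perceive_phonetic(grammar: Grammar, f1_bin: float, noise: NoiseModel, rng=None) -> str:
    """Single-level L1 perception: the least-penalized noisy phonetic vowel."""
    b = grammar.bin_index(f1_bin)
    rng = np.random.default_rng() if rng is None else rng
    noisy = grammar.perception[b] + noise.sd * rng.standard_normal(len(grammar.phonetic))
    winners = np.flatnonzero(noisy == noisy.min())
    k = winners[0] if len(winners) == 1 else winners[int(rng.integers(len(winners)))]
    return grammar.phonetic[int(k)]


class GrammarEvaluator:
    """Array-based evaluation engine used by the training loop and probes.

    Works on bin/pair/meaning indices rather than :class:`Path` objects, and
    draws noise only for the connections reachable from the current input
    (the noisy values of unreachable connections cannot influence the winner,
    so the outcome distribution is identical to distorting the whole
    grammar).  Equivalence with :func:`evaluate_optimal_path` on a shared
    noisy view is part of the test suite.
    """

    def __init__(self, grammar: Grammar, sd: float = 2.0):
        self.grammar = grammar
        self.sd = float(sd)
        self.n_phonetic = len(grammar.phonetic)
        if grammar.is_lexical:
            self.n_phonemic = len(grammar.phonemic)
            P, Q = self.n_phonetic, self.n_phonemic
            # path enumeration order matches enumerate_paths: i, then j, then m
            grid = np.mgrid[0:P, 0:Q, 0:2]
            self.I = grid[0].ravel()
            self.J = grid[1].ravel()
            self.M = grid[2].ravel()
            self.strata_cols = np.array(
                [grammar.strata["perception"], grammar.strata["phonemic"], grammar.strata["lexical"]]
            )

    # -------------------------------------------------------------- #

    def evaluate_l1(self, bin_idx: int, rng) -> int:
        """Index of the winning phonetic vowel for one L1 perception event."""
        row = self.grammar.perception[bin_idx]
        if self.sd > 0:
            row = row + self.sd * rng.standard_normal(self.n_phonetic)
        winners = np.flatnonzero(row == row.min())
        if len(winners) == 1:
            return int(winners[0])
        return int(winners[int(rng.integers(len(winners)))])

    def _draw_local_noise(self, bin_idx: int, pair_idx: int, rng):
        g, sd = self.grammar, self.sd
        nperc = g.perception[bin_idx] + sd * rng.standard_normal(self.n_phonetic)
        nphon = g.phonemic_table + sd * rng.standard_normal(g.phonemic_table.shape)
        nlex = g.lexical_table[pair_idx] + sd * rng.standard_normal((self.n_phonemic, 2))
        return nperc, nphon, nlex

    def evaluate(self, bin_idx: int, pair_idx: int, rng, restrict_m: int | None = None,
                 noisy=None):
        """Winning (phonetic, phonemic, meaning) index triple for one event.

        ``noisy`` may supply pre-drawn ``(nperc_row, nphon, nlex_pair)``
        arrays to evaluate on a fixed noise draw.
        """
        if noisy is None:
            noisy = self._draw_local_noise(bin_idx, pair_idx, rng)
        nperc, nphon, nlex = noisy
        I, J, M = self.I, self.J, self.M
        if restrict_m is not None:
            keep = M == restrict_m
            I, J, M = I[keep], J[keep], M[keep]
        V = np.empty((len(I), 3))
        V[:, 0] = nperc[I]
        V[:, 1] = nphon[I, J]
        V[:, 2] = nlex[J, M]
        # sort each row's (stratum, value) pairs worst-first
        ord1 = np.argsort(-V, axis=1, kind="stable")
        s1 = self.strata_cols[ord1]
        ord2 = np.argsort(-s1, axis=1, kind="stable")
        order = np.take_along_axis(ord1, ord2, axis=1)
        Vs = np.take_along_axis(V, order, axis=1)
        Ss = self.strata_cols[order]
        # lexicographic minimum over sorted profiles
        rank = np.lexsort((Vs[:, 2], Ss[:, 2], Vs[:, 1], Ss[:, 1], Vs[:, 0], Ss[:, 0]))
        top = rank[0]
        ties = np.flatnonzero((Ss == Ss[top]).all(axis=1) & (Vs == Vs[top]).all(axis=1))
        if len(ties) > 1:
            top = int(ties[int(rng.integers(len(ties)))])
        return int(I[top]), int(J[top]), int(M[top])

    def noisy_from_view(self, view: NoisyGrammarView, bin_idx: int, pair_idx: int):
        """Extract the local noisy arrays of a full-grammar view (for cross-checks)."""
        return (
            view.perception[bin_idx],
            view.phonemic_table,
            view.lexical_table[pair_idx],
        )
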