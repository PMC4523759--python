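"""Error-driven learning: the Gradual Learning Algorithm over path networks.

Learning is meaning-driven: after evaluating an input, the learner sees only
the intended target at the topmost trained level (the phonetic category in
the L1 phase, the word meaning in the L2 phase), never the intermediate
representations.  On a correct outcome nothing happens.  On an error the
learner re-applies fresh evaluation noise (resampling) and finds a target
parse — the optimal path among the candidates consistent with the intended
target — then weakens every connection on the erroneous winning path and
strengthens every connection on the target parse by the current plasticity.
Connections shared by both paths net exactly zero change.

Under the package's ranking-value polarity (lower = stronger), weakening
adds plasticity to a value and strengthening subtracts it.  Plasticity
starts at 0.1 and decays by a factor 0.7 every 10,000 tokens (applied
discretely at multiples of the decay interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .evaluation import (
    AcousticInput,
    GrammarEvaluator,
    NoiseModel,
    Path,
    evaluate_optimal_path,
)
from .grammar import Grammar

__all__ = [
    "PlasticitySchedule",
    "Token",
    "TrainingRecord",
    "plasticity_at",
    "interpretive_parse",
    "update_on_error",
    "train_learner",
    "write_trace",
]


def write_trace(records, path) -> None:
    """Write training-trace records as a tab-separated text table."""
    import pandas as pd

    pd.DataFrame(
        [(r.step, r.error, r.phonetic, r.meaning or "", r.plasticity) for r in records],
        columns=["step", "error", "winner_phonetic", "winner_meaning", "plasticity"],
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PlasticitySchedule:
    """Step-decaying learning rate: initial × factor^floor(step / interval)."""

    initial: float = 0.1
    decay_factor: float = 0.7
    decay_interval: int = 10_000

    def __post_init__(self):
        if self.initial <= 0 or not (0 < self.decay_factor <= 1) or self.decay_interval <= 0:
            raise ConfigurationError("invalid plasticity schedule")

    def at(self, step: int) -> float:
        if step < 0:
            raise ValueError("step must be non-negative")
        return self.initial * self.decay_factor ** (step // self.decay_interval)


def plasticity_at(schedule: PlasticitySchedule, step: int) -> float:
    """Plasticity in force at a given training step."""
    return schedule.at(step)


@dataclass(frozen=True)
class Token:
    """One training or test datum.

    L1 tokens pair an F1 bin with a target phonetic category and carry no
    carrier word; L2 tokens pair an F1 bin and a carrier minimal pair with a
    target meaning.  ``category`` retains the generating vowel category for
    diagnostics; the learner never sees it in the L2 phase.
    """

    phase: str
    f1_bin: float
    target: str
    carrier: str | None = None
    category: str | None = None

    def __post_init__(self):
        if self.phase not in ("L1", "L2"):
            raise ConfigurationError(f"unknown phase {self.phase!r}")
        if self.phase == "L1" and self.carrier is not None:
            raise ConfigurationError("L1 tokens carry no carrier word")
        if self.phase == "L2" and self.carrier is None:
            raise ConfigurationError("L2 tokens require a carrier pair")


@dataclass(frozen=True)
class TrainingRecord:
    """Per-token trace entry (emitted only when tracing is enabled)."""

    step: int
    error: bool
    phonetic: str
    meaning: str | None
    plasticity: float


def interpretive_parse(
    grammar: Grammar,
    inp: AcousticInput,
    target_meaning: str,
    noise: NoiseModel,
    rng=None,
    view=None,
) -> Path:
    """Find the target parse after a recognition error.

    Draws a fresh noisy view — independent of the draw used for the failed
    evaluation (resampling) — and returns the optimal path among only the
    candidates leading to ``target_meaning`` (nine in the standard network).
    """
    parse = evaluate_optimal_path(
        grammar, inp, noise, rng, restrict_to_meaning=target_meaning, view=view
    )
    return parse


def update_on_error(grammar: Grammar, wrong_path: Path, target_path: Path,
                    plasticity: float, sign: float = 1.0) -> Grammar:
    """Apply the GLA update for one error (in place).

    Every connection on the erroneous path is weakened (+plasticity on its
    ranking value) and every connection on the target parse strengthened
    (−plasticity); a connection on both paths nets a bit-exact zero change.
    ``sign=-1`` flips the update direction (sensitivity analysis only).
    """
    deltas: dict = {}
    for conn in wrong_path.connections:
        deltas[conn] = deltas.get(conn, 0.0) + plasticity
    for conn in target_path.connections:
        deltas[conn] = deltas.get(conn, 0.0) - plasticity
    for conn, d in deltas.items():
        if d != 0.0:
            grammar.add_to(conn, sign * d)
    return grammar


def _token_arrays(grammar: Grammar, tokens):
    """Convert a token stream to index arrays, validating phase consistency."""
    phases = {t.phase for t in tokens}
    if len(phases) > 1:
        raise ConfigurationError("mixed-phase token stream")
    phase = phases.pop()
    if phase == "L2" and not grammar.is_lexical:
        raise ConfigurationError("L2 tokens require a full (lexical) grammar")
    if phase == "L1" and grammar.is_lexical:
        raise ConfigurationError("L1 tokens require a perception-only grammar")
    bins = np.array([grammar.bin_index(t.f1_bin) for t in tokens], dtype=np.intp)
    if phase == "L1":
        pidx = {v: k for k, v in enumerate(grammar.phonetic)}
        targets = np.array([pidx[t.target] for t in tokens], dtype=np.intp)
        pairs = None
    else:
        pairs = np.array([grammar._pair_index[t.carrier] for t in tokens], dtype=np.intp)
        targets = np.array(
            [grammar.meaning_slot(t.carrier, t.target) for t in tokens], dtype=np.intp
        )
    return phase, bins, pairs, targets


def train_learner(
    grammar: Grammar,
    tokens,
    noise: NoiseModel,
    schedule: PlasticitySchedule,
    checkpoints=(),
    probe=None,
    rng=None,
    seed=None,
    update_sign: float = 1.0,
    trace: bool = False,
):
    """Run the full error-driven training loop over a token stream.

    The grammar is trained in place and returned together with the trace
    records (empty unless ``trace``).  ``probe(step, grammar)``, if given, is
    invoked at every step in ``checkpoints`` (before the step's token is
    processed, and once more after the last token if the stream length is a
    checkpoint); probes must not mutate the grammar and should use their own
    RNG stream.

    Separate noise substreams are used for evaluation and for parse
    resampling, spawned from ``rng`` (or from ``seed``).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rng_eval, rng_parse = rng.spawn(2)
    phase, bins, pairs, targets = _token_arrays(grammar, tokens)
    checkpoints = set(checkpoints)
    records: list[TrainingRecord] = []
    ev = GrammarEvaluator(grammar, noise.sd)
    sign = float(update_sign)

    if phase == "L1":
        perc = grammar.perception
        for step in range(len(bins)):
            if probe is not None and step in checkpoints:
                probe(step, grammar)
            b, t = bins[step], targets[step]
            w = ev.evaluate_l1(b, rng_eval)
            err = w != t
            if err:
                # the parse restricted to the target category is that single
                # path; resampled noise cannot change it
                p = schedule.at(step)
                perc[b, w] += sign * p
                perc[b, t] -= sign * p
            if trace:
                records.append(
                    TrainingRecord(step, bool(err), grammar.phonetic[w], None,
                                   schedule.at(step))
                )
    else:
        for step in range(len(bins)):
            if probe is not None and step in checkpoints:
                probe(step, grammar)
            b, pr, t = bins[step], pairs[step], targets[step]
            i, j, m = ev.evaluate(b, pr, rng_eval)
            err = m != t
            if err:
                i2, j2, m2 = ev.evaluate(b, pr, rng_parse, restrict_m=t)
                p = schedule.at(step) * sign
                if i != i2:
                    grammar.perception[b, i] += p
                    grammar.perception[b, i2] -= p
                if (i, j) != (i2, j2):
                    grammar.phonemic_table[i, j] += p
                    grammar.phonemic_table[i2, j2] -= p
                if (j, m) != (j2, m2):
                    grammar.lexical_table[pr, j, m] += p
                    grammar.lexical_table[pr, j2, m2] -= p
            if trace:
                pair = grammar.pairs[pr]
                records.append(
                    TrainingRecord(step, bool(err), grammar.phonetic[i],
                                   pair.meanings[m], schedule.at(step))
                )
    if probe is not None and len(bins) in checkpoints:
        probe(len(bins), grammar)
    return grammar, records
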