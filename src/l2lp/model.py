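"""Model/Results interface over the learning simulator.

Two model classes wrap the two training phases the way statistical modelling
packages wrap an estimator: a model object is built from data (a token
corpus), ``fit()`` runs the error-driven training and returns a results
object carrying the trained grammar, held-out accuracy curves, diagnostics
and a ``summary()`` table, with simulation probes and plotting hanging off
the results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import split_train_test, sample_training_stream
from .errors import ConfigurationError
from .evaluation import NoiseModel
from .experiment import categorization_curve, ih_area, recognition_rate
from .grammar import Grammar, build_l1_grammar, default_grid, full_copy_to_l2
from .learning import PlasticitySchedule, Token, train_learner

__all__ = [
    "VowelPerceptionModel",
    "VowelPerceptionResults",
    "LexicalRecognitionModel",
    "LexicalRecognitionResults",
]

_CHECKPOINT_LADDER = (0, 1000, 2000, 4000, 8000, 10_000, 20_000, 40_000)


def _checkpoints_for(n_iterations: int, checkpoints):
    if checkpoints is not None:
        return tuple(checkpoints)
    pts = [c for c in _CHECKPOINT_LADDER if c <= n_iterations]
    if n_iterations not in pts:
        pts.append(n_iterations)
    return tuple(pts)


def _tokens_from_dataframe(df: pd.DataFrame, phase: str):
    tokens = []
    for _, row in df.iterrows():
        if phase == "L1":
            tokens.append(Token("L1", float(row["f1_bark_bin"]), str(row["category"]),
                                category=str(row["category"])))
        else:
            tokens.append(Token("L2", float(row["f1_bark_bin"]), str(row["meaning"]),
                                carrier=str(row["carrier"]),
                                category=str(row.get("category", "")) or None))
    return tokens


class VowelPerceptionModel:
    """L1 phonetic categorization trained on labelled [acoustic] ~ /phonetic/ pairs.

    Parameters
    ----------
    tokens
        L1 tokens (e.g. from :func:`l2lp.corpus.generate_corpus`).
    inventory
        Phonetic vowel labels ordered by height (low F1 first); inferred
        from the tokens (ordered by each category's mean F1) when omitted.
    """

    def __init__(self, tokens, inventory=None, grid=None, initial_value: float = 100.0,
                 noise_sd: float = 2.0, plasticity: PlasticitySchedule | None = None):
        self.tokens = list(tokens)
        if not self.tokens:
            raise ConfigurationError("no training tokens")
        if any(t.phase != "L1" for t in self.tokens):
            raise ConfigurationError("VowelPerceptionModel expects L1 tokens")
        if inventory is not None:
            self.inventory = tuple(inventory)
        else:
            # order categories by mean F1 so that index 1 of a three-vowel
            # inventory is the middle (height-intermediate) vowel
            sums: dict[str, list[float]] = {}
            for t in self.tokens:
                sums.setdefault(t.target, []).append(t.f1_bin)
            self.inventory = tuple(sorted(sums, key=lambda c: np.mean(sums[c])))
        self.grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
        self.initial_value = initial_value
        self.noise_sd = noise_sd
        self.plasticity = plasticity or PlasticitySchedule()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "VowelPerceptionModel":
        """Build from a table with columns ``f1_bark_bin`` and ``category``."""
        return cls(_tokens_from_dataframe(df, "L1"), **kw)

    def fit(self, n_iterations: int = 40_000, seed=None, train_fraction: float = 0.9,
            checkpoints=None) -> "VowelPerceptionResults":
        """Split the corpus, train on a resampled stream, probe held-out accuracy."""
        rng = np.random.default_rng(seed)
        rng_split, rng_train, rng_probe = rng.spawn(3)
        train, test = split_train_test(self.tokens, train_fraction, rng_split)
        stream = sample_training_stream(train, n_iterations, rng_split)
        grammar = build_l1_grammar(self.inventory, self.grid, self.initial_value)
        curve = []

        def probe(step, g):
            curve.append((step, recognition_rate(g, test, self.noise_sd, rng_probe)))

        train_learner(grammar, stream, NoiseModel(self.noise_sd), self.plasticity,
                      checkpoints=_checkpoints_for(n_iterations, checkpoints),
                      probe=probe, rng=rng_train)
        return VowelPerceptionResults(self, grammar, curve, n_iterations, len(train), len(test))


@dataclass
class VowelPerceptionResults:
    """Trained L1 perception grammar with its held-out accuracy curve."""

    model: VowelPerceptionModel
    grammar: Grammar
    _curve: list
    n_iterations: int
    n_train: int
    n_test: int

    @property
    def accuracy_curve(self) -> pd.DataFrame:
        return pd.DataFrame(self._curve, columns=["step", "accuracy"])

    @property
    def final_accuracy(self) -> float:
        return self._curve[-1][1]

    def categorization(self, n_probe_samples: int = 200, seed=None) -> pd.DataFrame:
        """Phonetic categorization curve of the trained grammar."""
        return categorization_curve(self.grammar, n_probe_samples=n_probe_samples,
                                    noise_sd=self.model.noise_sd,
                                    rng=np.random.default_rng(seed))

    def summary(self) -> str:
        head = "Vowel perception model (L1 phase)"
        lines = [head, "=" * len(head),
                 f"phonetic inventory     : {', '.join(self.model.inventory)}",
                 f"corpus (train / test)  : {self.n_train} / {self.n_test} tokens",
                 f"training iterations    : {self.n_iterations}",
                 f"evaluation noise sd    : {self.model.noise_sd}",
                 "held-out identification accuracy:"]
        for step, acc in self._curve:
            lines.append(f"  step {step:>7d} : {100 * acc:5.1f}%")
        return "\n".join(lines)

    def plot_curve(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.accuracy_curve
        ax.plot(df["step"], 100 * df["accuracy"], marker="o")
        ax.set_xlabel("training step")
        ax.set_ylabel("held-out accuracy (%)")
        ax.set_title("L1 identification accuracy")
        return ax


class LexicalRecognitionModel:
    """L2 word recognition trained on meaning-labelled minimal-pair tokens.

    Starts from a Full Copy of a trained L1 perception grammar; the only
    learning signal is whether the intended meaning was recognized.
    ``mode`` selects sequential or interactive processing.
    """

    def __init__(self, l1_grammar: Grammar, tokens, pairs, mode: str = "sequential",
                 faithful_value: float = 95.0, unfaithful_value: float = 105.0,
                 lexical_value: float = 100.0, noise_sd: float = 2.0,
                 plasticity: PlasticitySchedule | None = None):
        self.l1_grammar = l1_grammar
        self.tokens = list(tokens)
        if not self.tokens:
            raise ConfigurationError("no training tokens")
        if any(t.phase != "L2" for t in self.tokens):
            raise ConfigurationError("LexicalRecognitionModel expects L2 tokens")
        self.pairs = tuple(pairs)
        self.mode = mode
        self.faithful_value = faithful_value
        self.unfaithful_value = unfaithful_value
        self.lexical_value = lexical_value
        self.noise_sd = noise_sd
        self.plasticity = plasticity or PlasticitySchedule()

    @classmethod
    def from_dataframe(cls, l1_grammar, df: pd.DataFrame, pairs, **kw):
        """Build from a table with columns ``f1_bark_bin``, ``carrier``, ``meaning``."""
        return cls(l1_grammar, _tokens_from_dataframe(df, "L2"), pairs, **kw)

    def fit(self, n_iterations: int = 40_000, seed=None, train_fraction: float = 0.9,
            checkpoints=None, curve_samples: int = 200) -> "LexicalRecognitionResults":
        """Full-copy, train on a resampled stream, probe recognition and curves."""
        rng = np.random.default_rng(seed)
        rng_split, rng_train, rng_probe, rng_curve = rng.spawn(4)
        train, test = split_train_test(self.tokens, train_fraction, rng_split)
        stream = sample_training_stream(train, n_iterations, rng_split)
        grammar = full_copy_to_l2(self.l1_grammar, self.pairs,
                                  faithful_value=self.faithful_value,
                                  unfaithful_value=self.unfaithful_value,
                                  lexical_value=self.lexical_value, mode=self.mode)
        curve = []

        def probe(step, g):
            curve.append((step, recognition_rate(g, test, self.noise_sd, rng_probe)))

        train_learner(grammar, stream, NoiseModel(self.noise_sd), self.plasticity,
                      checkpoints=_checkpoints_for(n_iterations, checkpoints),
                      probe=probe, rng=rng_train)
        final_curve = categorization_curve(grammar, n_probe_samples=curve_samples,
                                           noise_sd=self.noise_sd, rng=rng_curve)
        return LexicalRecognitionResults(self, grammar, curve, final_curve,
                                         n_iterations, len(train), len(test))


@dataclass
class LexicalRecognitionResults:
    """Trained L2 grammar with recognition curve and final categorization."""

    model: LexicalRecognitionModel
    grammar: Grammar
    _curve: list
    categorization: pd.DataFrame
    n_iterations: int
    n_train: int
    n_test: int

    @property
    def recognition_curve(self) -> pd.DataFrame:
        return pd.DataFrame(self._curve, columns=["step", "accuracy"])

    @property
    def final_accuracy(self) -> float:
        return self._curve[-1][1]

    def ih_area(self, category: str = "ɪ") -> float:
        """Area under a phonetic category's final categorization curve (Bark)."""
        return ih_area(self.categorization, category=category)

    def summary(self) -> str:
        head = f"Lexical recognition model (L2 phase, {self.model.mode})"
        lines = [head, "=" * len(head),
                 f"minimal pairs          : {len(self.model.pairs)}",
                 f"corpus (train / test)  : {self.n_train} / {self.n_test} tokens",
                 f"training iterations    : {self.n_iterations}",
                 f"evaluation noise sd    : {self.model.noise_sd}",
                 "held-out recognition accuracy:"]
        for step, acc in self._curve:
            lines.append(f"  step {step:>7d} : {100 * acc:5.1f}%")
        middle = self.model.l1_grammar.phonetic[1] if len(self.model.l1_grammar.phonetic) == 3 else None
        if middle is not None:
            lines.append(f"final /{middle}/ categorization area : {self.ih_area(middle):.3f} Bark")
        return "\n".join(lines)

    def plot_curve(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.recognition_curve
        ax.plot(df["step"], 100 * df["accuracy"], marker="o")
        ax.set_xlabel("training step")
        ax.set_ylabel("held-out recognition (%)")
        ax.set_title(f"L2 lexical recognition ({self.model.mode})")
        return ax

    def plot_categorization(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cat, sub in self.categorization.groupby("category"):
            ax.plot(sub["bin"], sub["proportion"], label=f"/{cat}/")
        ax.set_xlabel("F1 (Bark)")
        ax.set_ylabel("response proportion")
        ax.set_title(f"Phonetic categorization ({self.model.mode})")
        ax.legend()
        return ax
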