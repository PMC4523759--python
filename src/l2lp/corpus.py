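"""Synthetic vowel-production corpora for the L1 (Dutch) and L2 (Spanish) phases.

Each vowel category is emulated as a Gaussian over F1 on the Bark scale;
samples are discretized to the grammar's 0.1-Bark grid on [2.0, 8.0].  The
defaults emulate female Dutch /i/, /ɪ/, /ɛ/ and Spanish /i/, /e/
front-vowel productions with the overlap structure that caps attainable
accuracy near 80% (Dutch three-way) and 85% (Spanish two-way) — see the
probability-matching oracle in :mod:`l2lp.experiment`.

L2 tokens additionally carry a uniformly sampled carrier minimal pair and
the meaning congruent with the generating vowel category; the learner sees
only the carrier, the F1 bin and the meaning.

User-supplied token tables (delimited text, F1 in Hz or Bark) are accepted
through :func:`read_tokens`; Hz values are converted with Traunmüller's
(1990) closed form and binned on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .grammar import BARK_MAX, BARK_MIN, MinimalPair, default_grid, default_lexicon
from .learning import Token

__all__ = [
    "VowelDistribution",
    "CorpusConfig",
    "DUTCH_DISTRIBUTIONS",
    "SPANISH_DISTRIBUTIONS",
    "dutch_config",
    "spanish_config",
    "hz_to_bark",
    "bark_to_hz",
    "bin_bark",
    "generate_corpus",
    "split_train_test",
    "sample_training_stream",
    "write_tokens",
    "read_tokens",
]


@dataclass(frozen=True)
class VowelDistribution:
    """Gaussian F1 distribution of one vowel category (Bark)."""

    category: str
    mean: float
    sd: float
    weight: float = 1.0

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigurationError("distribution sd must be positive")
        if self.weight <= 0:
            raise ConfigurationError("distribution weight must be positive")


#: Female Dutch front vowels /i/, /ɪ/, /ɛ/ on the F1 continuum.
DUTCH_DISTRIBUTIONS = (
    VowelDistribution("i", 3.0, 0.55),
    VowelDistribution("ɪ", 4.3, 0.55),
    VowelDistribution("ɛ", 5.7, 0.55),
)

#: Female Spanish front vowels /i/, /e/.
SPANISH_DISTRIBUTIONS = (
    VowelDistribution("i", 3.5, 0.6),
    VowelDistribution("e", 5.0, 0.6),
)


@dataclass(frozen=True)
class CorpusConfig:
    """Configuration of one synthetic corpus.

    ``n_tokens`` is the total corpus size; per-category counts follow the
    (normalized) mixture weights by largest-remainder apportionment, so the
    equal-weight defaults give exactly ``n_tokens / n_categories`` tokens per
    vowel.  For an L2 corpus the first distribution is the /i/-like category
    (mapped to each pair's i-meaning) and the second the /e/-like one.
    """

    phase: str
    distributions: tuple[VowelDistribution, ...]
    n_tokens: int
    pairs: tuple[MinimalPair, ...] | None = None
    train_fraction: float = 0.9
    grid: np.ndarray = field(default_factory=default_grid)
    seed: int | None = None

    def __post_init__(self):
        if self.phase not in ("L1", "L2"):
            raise ConfigurationError(f"unknown phase {self.phase!r}")
        if not self.distributions:
            raise ConfigurationError("at least one vowel distribution is required")
        if self.n_tokens <= 0:
            raise ConfigurationError("n_tokens must be positive")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.phase == "L2":
            if not self.pairs:
                raise ConfigurationError("an L2 corpus requires a minimal-pair lexicon")
            if len(self.distributions) != 2:
                raise ConfigurationError("an L2 corpus requires exactly two vowel categories")


def dutch_config(n_tokens: int = 1500, **kw) -> CorpusConfig:
    """Default Dutch (L1) corpus: 500 tokens per vowel."""
    return CorpusConfig("L1", DUTCH_DISTRIBUTIONS, n_tokens, **kw)


def spanish_config(n_tokens: int = 1000, pairs=None, **kw) -> CorpusConfig:
    """Default Spanish (L2) corpus: 500 tokens per vowel, default lexicon."""
    return CorpusConfig("L2", SPANISH_DISTRIBUTIONS, n_tokens,
                        pairs=tuple(pairs) if pairs is not None else default_lexicon(), **kw)


def hz_to_bark(f1):
    """Traunmüller's (1990) Hz-to-Bark conversion: z = 26.81·f/(1960+f) − 0.53."""
    f1 = np.asarray(f1, dtype=float)
    if np.any(f1 <= 0):
        raise ValueError("frequency must be positive")
    z = 26.81 * f1 / (1960.0 + f1) - 0.53
    return float(z) if z.ndim == 0 else z


def bark_to_hz(z):
    """Inverse of :func:`hz_to_bark`."""
    z = np.asarray(z, dtype=float)
    f = 1960.0 * (z + 0.53) / (26.28 - z)
    return float(f) if f.ndim == 0 else f


def bin_bark(z, grid=None):
    """Round Bark values to the nearest 0.1 bin (ties away from zero) and clip.

    Out-of-range values are clipped to the grid edges rather than rejected;
    for the default distributions the edge mass is negligible.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    z = np.asarray(z, dtype=float)
    rounded = np.sign(z) * np.floor(np.abs(z) * 10.0 + 0.5) / 10.0
    clipped = np.clip(rounded, grid[0], grid[-1])
    idx = np.rint((clipped - grid[0]) * 10.0).astype(int)
    out = grid[idx]
    return float(out) if out.ndim == 0 else out


def _category_counts(config: CorpusConfig) -> list[int]:
    w = np.array([d.weight for d in config.distributions], dtype=float)
    w = w / w.sum()
    raw = w * config.n_tokens
    counts = np.floor(raw).astype(int)
    remainder = config.n_tokens - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts.tolist()


def generate_corpus(config: CorpusConfig, rng=None) -> list[Token]:
    """Sample a synthetic corpus of tokens from the configured mixture.

    Each token's F1 is drawn from its category's Gaussian and binned; L1
    tokens are targeted with the category itself, L2 tokens with a uniformly
    sampled carrier pair and the meaning congruent with the category.  The
    generating category is retained on every token.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    counts = _category_counts(config)
    tokens: list[Token] = []
    for dist, count, slot in zip(config.distributions, counts, range(len(counts))):
        f1 = rng.normal(dist.mean, dist.sd, size=count)
        binned = np.atleast_1d(bin_bark(f1, config.grid))
        if config.phase == "L1":
            tokens.extend(
                Token("L1", float(b), dist.category, category=dist.category) for b in binned
            )
        else:
            pair_idx = rng.integers(len(config.pairs), size=count)
            for b, k in zip(binned, pair_idx):
                pair = config.pairs[int(k)]
                meaning = pair.meanings[slot]
                tokens.append(
                    Token("L2", float(b), meaning, carrier=pair.pair_id, category=dist.category)
                )
    perm = rng.permutation(len(tokens))
    return [tokens[int(k)] for k in perm]


def split_train_test(tokens, fraction: float = 0.9, rng=None, seed=None):
    """Random disjoint train/test partition with |train| = round(fraction · n)."""
    if not (0.0 < fraction < 1.0):
        raise ConfigurationError("fraction must lie in (0, 1)")
    if len(tokens) == 0:
        raise ValueError("cannot split an empty token list")
    rng = np.random.default_rng(seed) if rng is None else rng
    perm = rng.permutation(len(tokens))
    n_train = int(round(fraction * len(tokens)))
    n_train = min(max(n_train, 1), len(tokens) - 1)
    train = [tokens[int(k)] for k in perm[:n_train]]
    test = [tokens[int(k)] for k in perm[n_train:]]
    return train, test


def sample_training_stream(train, n_iterations: int, rng=None, seed=None):
    """Draw a training stream of tokens uniformly with replacement."""
    if len(train) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(seed) if rng is None else rng
    idx = rng.integers(len(train), size=int(n_iterations))
    return [train[int(k)] for k in idx]


_COLUMNS = ["phase", "category", "f1_bark_bin", "carrier", "meaning"]


def write_tokens(tokens, path) -> None:
    """Write tokens as a tab-separated table (phase, category, f1, carrier, meaning)."""
    rows = [
        (t.phase, t.category or "", t.f1_bin, t.carrier or "",
         t.target if t.phase == "L2" else "")
        for t in tokens
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tokens(path, f1_unit: str = "bark", grid=None) -> list[Token]:
    """Read a token table; ``f1_unit="hz"`` converts and bins on load."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"category": str, "carrier": str, "meaning": str})
    f1 = df["f1_bark_bin"].to_numpy(dtype=float)
    if f1_unit == "hz":
        f1 = hz_to_bark(f1)
    elif f1_unit != "bark":
        raise ConfigurationError(f"unknown F1 unit {f1_unit!r}")
    f1 = np.atleast_1d(bin_bark(f1, grid))
    tokens = []
    for (_, row), b in zip(df.iterrows(), f1):
        if row["phase"] == "L1":
            tokens.append(Token("L1", float(b), row["category"], category=row["category"]))
        else:
            tokens.append(
                Token("L2", float(b), row["meaning"], carrier=row["carrier"],
                      category=row["category"] or None)
            )
    return tokens
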