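"""Four-level connection-network grammars for vowel perception and recognition.

A grammar is the learner's entire knowledge state: weighted connections
between units on four ordered levels of representation,

    [acoustic] -> /phonetic/ -> |phonemic| -> <lexical>.

The acoustic level is a discretized F1 (first formant) continuum on the
psychoacoustic Bark scale; the phonetic level holds language-specific vowel
categories; the phonemic level holds canonical word-form vowels; the lexical
level holds word meanings.  Knowledge lives entirely in connection strengths:
the units themselves are fixed and are never created or deleted.

Ranking-value polarity
----------------------
A connection's ``ranking_value`` is the penalty rank of a negative constraint
against using that mapping, so a LOWER value means a STRONGER connection.
This is the reading under which the faithful phonetic-to-phonemic mappings
(initialized at 95) are stronger than the unfaithful ones (initialized at
105), and it fixes the sign convention used throughout: learning strengthens
a connection by subtracting plasticity from its value and weakens it by
adding.

Each connection additionally carries a small integer *stratum*; connections
in a higher stratum strictly dominate all connections in lower strata during
evaluation, whatever their (noise-distorted) ranking values.  Putting the
acoustic-to-phonetic connections in a stratum of their own makes processing
sequential (perception is settled before lexical recognition); a single
shared stratum makes processing interactive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "BARK_MIN",
    "BARK_MAX",
    "BARK_STEP",
    "Level",
    "AcousticInput",
    "MinimalPair",
    "Grammar",
    "default_grid",
    "default_lexicon",
    "build_l1_grammar",
    "full_copy_to_l2",
    "connection_strength_order",
]

BARK_MIN = 2.0
BARK_MAX = 8.0
BARK_STEP = 0.1

#: Dutch front-vowel inventory on the F1 continuum (high to low).
DUTCH_FRONT_VOWELS = ("i", "ɪ", "ɛ")


def default_grid() -> np.ndarray:
    """The 61-point F1 grid from 2.0 to 8.0 Bark in 0.1-Bark bins."""
    return np.arange(20, 81) / 10.0


class Level(enum.IntEnum):
    """The four totally ordered levels of representation."""

    ACOUSTIC = 0
    PHONETIC = 1
    PHONEMIC = 2
    LEXICAL = 3


@dataclass(frozen=True)
class AcousticInput:
    """One acoustic stimulus: an F1 bin, plus a carrier minimal pair in L2 mode.

    Carrier words are acoustically invariant; only the front vowel's F1
    varies, so the carrier merely selects the subnetwork (the minimal pair's
    word forms and meanings) in which the vowel is embedded.
    """

    f1_bin: float
    carrier: str | None = None


@dataclass(frozen=True)
class MinimalPair:
    """A minimal pair of L2 words differing only in their front vowel.

    ``i_form``/``e_form`` are the two word-form labels (e.g. *chica* /
    *checa*); ``i_meaning``/``e_meaning`` the corresponding meanings.  Each
    pair contributes two lexical units and, in the grammar, one phonemic
    word-form unit per phonetic vowel quality.
    """

    pair_id: str
    i_form: str
    e_form: str
    i_meaning: str
    e_meaning: str

    @property
    def meanings(self) -> tuple[str, str]:
        return (self.i_meaning, self.e_meaning)


def default_lexicon(n_synthetic_pairs: int = 20) -> tuple[MinimalPair, ...]:
    """The default carrier lexicon: *chica*/*checa* plus synthetic pairs.

    The worked example pair [tʃVka] (girl / Czech.F) is always included;
    ``n_synthetic_pairs`` schematic pairs pair_01..pair_NN are added.
    """
    pairs = [MinimalPair("chica-checa", "tʃika", "tʃeka", "girl", "czech.f")]
    for k in range(1, n_synthetic_pairs + 1):
        pid = f"pair_{k:02d}"
        pairs.append(MinimalPair(pid, f"{pid}/i/", f"{pid}/e/", f"{pid}.i", f"{pid}.e"))
    return tuple(pairs)


class Grammar:
    """A stratified, weighted connection network over the four levels.

    Parameters
    ----------
    bins
        The acoustic F1 grid (Bark values).
    phonetic
        Phonetic vowel labels.
    perception
        Array of shape ``(n_bins, n_phonetic)`` of ranking values for the
        acoustic-to-phonetic connections.
    phonemic, phonemic_table
        Phonemic vowel labels and the ``(n_phonetic, n_phonemic)`` table of
        phonetic-to-phonemic ranking values (``None`` for an L1
        perception-only grammar).
    pairs, lexical_table
        Minimal pairs and the ``(n_pairs, n_phonemic, 2)`` table of
        phonemic-to-lexical ranking values; the last axis indexes the pair's
        two meanings in ``(i_meaning, e_meaning)`` order.
    strata
        Mapping from table name (``perception``/``phonemic``/``lexical``) to
        stratum index; higher strata dominate in evaluation.

    Perception and phonemic connections pertain only to front-vowel
    representations and are shared across carrier words; lexical connections
    are specific to each minimal pair's subnetwork.
    """

    def __init__(
        self,
        bins,
        phonetic,
        perception,
        phonemic=None,
        phonemic_table=None,
        pairs=None,
        lexical_table=None,
        strata=None,
    ):
        self.bins = np.asarray(bins, dtype=float)
        self.phonetic = tuple(phonetic)
        self.perception = np.asarray(perception, dtype=float)
        if not self.phonetic:
            raise ConfigurationError("phonetic inventory must be non-empty")
        if self.perception.shape != (len(self.bins), len(self.phonetic)):
            raise ConfigurationError(
                f"perception table shape {self.perception.shape} does not match "
                f"({len(self.bins)}, {len(self.phonetic)})"
            )

        self.phonemic = tuple(phonemic) if phonemic is not None else None
        self.phonemic_table = (
            np.asarray(phonemic_table, dtype=float) if phonemic_table is not None else None
        )
        self.pairs = tuple(pairs) if pairs is not None else None
        self.lexical_table = (
            np.asarray(lexical_table, dtype=float) if lexical_table is not None else None
        )
        self.strata = dict(strata) if strata is not None else {}
        for name in ("perception", "phonemic", "lexical"):
            self.strata.setdefault(name, 0)

        if (self.phonemic is None) != (self.phonemic_table is None):
            raise ConfigurationError("phonemic inventory and table must come together")
        if (self.pairs is None) != (self.lexical_table is None):
            raise ConfigurationError("pairs and lexical table must come together")
        if self.phonemic_table is not None and self.phonemic_table.shape != (
            len(self.phonetic),
            len(self.phonemic),
        ):
            raise ConfigurationError("phonemic table shape mismatch")
        if self.pairs is not None:
            ids = [p.pair_id for p in self.pairs]
            if len(set(ids)) != len(ids):
                raise ConfigurationError("duplicate minimal-pair ids")
            if self.lexical_table.shape != (len(self.pairs), len(self.phonemic), 2):
                raise ConfigurationError("lexical table shape mismatch")

        self._phonetic_index = {v: k for k, v in enumerate(self.phonetic)}
        self._phonemic_index = (
            {v: k for k, v in enumerate(self.phonemic)} if self.phonemic else {}
        )
        self._pair_index = (
            {p.pair_id: k for k, p in enumerate(self.pairs)} if self.pairs else {}
        )

    # ------------------------------------------------------------------ #
    # lookups

    @property
    def is_lexical(self) -> bool:
        """Whether the grammar has the full network up to the lexical level."""
        return self.pairs is not None

    def bin_index(self, f1_bin: float) -> int:
        idx = int(round((f1_bin - self.bins[0]) / BARK_STEP))
        if idx < 0 or idx >= len(self.bins) or abs(self.bins[idx] - f1_bin) > 1e-9:
            raise KeyError(f"F1 bin {f1_bin} is not on the grammar's grid")
        return idx

    def pair(self, pair_id: str) -> MinimalPair:
        try:
            return self.pairs[self._pair_index[pair_id]]
        except (TypeError, KeyError):
            raise KeyError(f"unknown carrier pair {pair_id!r}") from None

    def meaning_slot(self, pair_id: str, meaning: str) -> int:
        pair = self.pair(pair_id)
        try:
            return pair.meanings.index(meaning)
        except ValueError:
            raise KeyError(f"meaning {meaning!r} does not belong to pair {pair_id!r}") from None

    def _locate(self, conn):
        """Resolve a connection key to (table array, index tuple)."""
        kind = conn[0]
        if kind == "perception":
            return self.perception, (self.bin_index(conn[1]), self._phonetic_index[conn[2]])
        if kind == "phonemic":
            return self.phonemic_table, (
                self._phonetic_index[conn[1]],
                self._phonemic_index[conn[2]],
            )
        if kind == "lexical":
            return self.lexical_table, (
                self._pair_index[conn[1]],
                self._phonemic_index[conn[2]],
                self.meaning_slot(conn[1], conn[3]),
            )
        raise KeyError(f"unknown connection kind {kind!r}")

    def value(self, conn) -> float:
        """Stored ranking value of a connection key."""
        table, idx = self._locate(conn)
        return float(table[idx])

    def add_to(self, conn, delta: float) -> None:
        """Add ``delta`` to a connection's stored ranking value (in place)."""
        table, idx = self._locate(conn)
        table[idx] += delta

    def stratum_of(self, conn) -> int:
        return self.strata[conn[0]]

    @property
    def n_connections(self) -> int:
        n = self.perception.size
        if self.phonemic_table is not None:
            n += self.phonemic_table.size
        if self.lexical_table is not None:
            n += self.lexical_table.size
        return n

    def copy(self) -> "Grammar":
        """An independent deep copy (tables are not shared)."""
        return Grammar(
            self.bins.copy(),
            self.phonetic,
            self.perception.copy(),
            phonemic=self.phonemic,
            phonemic_table=None if self.phonemic_table is None else self.phonemic_table.copy(),
            pairs=self.pairs,
            lexical_table=None if self.lexical_table is None else self.lexical_table.copy(),
            strata=dict(self.strata),
        )

    # ------------------------------------------------------------------ #
    # dump / restore

    def to_frame(self) -> pd.DataFrame:
        """All connections as a table (table, key1, key2, key3, ranking_value, stratum)."""
        rows = []
        s = self.strata
        for b, f1 in enumerate(self.bins):
            for p, pv in enumerate(self.phonetic):
                rows.append(("perception", repr(float(f1)), pv, "", self.perception[b, p], s["perception"]))
        if self.phonemic is not None:
            for p, pv in enumerate(self.phonetic):
                for q, qv in enumerate(self.phonemic):
                    rows.append(("phonemic", pv, qv, "", self.phonemic_table[p, q], s["phonemic"]))
        if self.pairs is not None:
            for k, pair in enumerate(self.pairs):
                for q, qv in enumerate(self.phonemic):
                    for m, meaning in enumerate(pair.meanings):
                        rows.append(("lexical", pair.pair_id, qv, meaning, self.lexical_table[k, q, m], s["lexical"]))
        return pd.DataFrame(rows, columns=["table", "key1", "key2", "key3", "ranking_value", "stratum"])

    def dump(self, path) -> None:
        """Write the grammar as a tab-separated text table (lossless floats)."""
        frame = self.to_frame()
        frame["ranking_value"] = [repr(float(v)) for v in frame["ranking_value"]]
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Grammar":
        perc = frame[frame["table"] == "perception"]
        bins = list(dict.fromkeys(float(v) for v in perc["key1"]))
        phonetic = list(dict.fromkeys(perc["key2"]))
        perception = np.empty((len(bins), len(phonetic)))
        bi = {repr(v): k for k, v in enumerate(bins)}
        pi = {v: k for k, v in enumerate(phonetic)}
        for _, r in perc.iterrows():
            perception[bi[repr(float(r.key1))], pi[r.key2]] = float(r.ranking_value)
        strata = {"perception": int(perc["stratum"].iloc[0])}

        phonemic = phonemic_table = pairs = lexical_table = None
        phon = frame[frame["table"] == "phonemic"]
        if len(phon):
            phonemic = list(dict.fromkeys(phon["key2"]))
            qi = {v: k for k, v in enumerate(phonemic)}
            phonemic_table = np.empty((len(phonetic), len(phonemic)))
            for _, r in phon.iterrows():
                phonemic_table[pi[r.key1], qi[r.key2]] = float(r.ranking_value)
            strata["phonemic"] = int(phon["stratum"].iloc[0])
        lex = frame[frame["table"] == "lexical"]
        if len(lex):
            pair_ids = list(dict.fromkeys(lex["key1"]))
            meanings = {pid: list(dict.fromkeys(lex[lex["key1"] == pid]["key3"])) for pid in pair_ids}
            # word-form labels are not part of the numeric state; regenerate
            # placeholder forms from the pair id
            pairs = [
                MinimalPair(pid, f"{pid}:i", f"{pid}:e", meanings[pid][0], meanings[pid][1])
                for pid in pair_ids
            ]
            ki = {pid: k for k, pid in enumerate(pair_ids)}
            lexical_table = np.empty((len(pairs), len(phonemic), 2))
            for _, r in lex.iterrows():
                m = meanings[r.key1].index(r.key3)
                lexical_table[ki[r.key1], qi[r.key2], m] = float(r.ranking_value)
            strata["lexical"] = int(lex["stratum"].iloc[0])

        return cls(
            bins, phonetic, perception,
            phonemic=phonemic, phonemic_table=phonemic_table,
            pairs=pairs, lexical_table=lexical_table, strata=strata,
        )

    @classmethod
    def restore(cls, path) -> "Grammar":
        """Read a grammar previously written by :meth:`dump`."""
        frame = pd.read_csv(
            path, sep="\t", keep_default_na=False,
            # ranking values are parsed with Python's float() so that the
            # repr round-trip is bit-exact
            dtype={"key1": str, "key2": str, "key3": str, "ranking_value": str},
        )
        return cls.from_frame(frame)


def build_l1_grammar(phonetic_inventory, bin_grid=None, initial_value: float = 100.0) -> Grammar:
    """A fresh perception-only (L1) grammar with all connections equal.

    Every acoustic-to-phonetic ranking value starts at ``initial_value``
    (default 100), so initial categorization is decided purely by evaluation
    noise.
    """
    phonetic = tuple(phonetic_inventory)
    if not phonetic:
        raise ConfigurationError("phonetic inventory must be non-empty")
    bins = default_grid() if bin_grid is None else np.asarray(bin_grid, dtype=float)
    perception = np.full((len(bins), len(phonetic)), float(initial_value))
    return Grammar(bins, phonetic, perception)


def full_copy_to_l2(
    l1: Grammar,
    pairs,
    phonemic_inventory=None,
    faithful_value: float = 95.0,
    unfaithful_value: float = 105.0,
    lexical_value: float = 100.0,
    mode: str = "sequential",
) -> Grammar:
    """Initialize an L2 grammar as a Full Copy of an L1 perception grammar.

    The perception table is copied verbatim (the copy is independent: later
    L2 learning never touches the L1 grammar).  The phonetic-to-phonemic
    table gets ``faithful_value`` where the two labels match and
    ``unfaithful_value`` elsewhere — a quantitative bias toward faithful
    mappings that learning may erode.  All phonemic-to-lexical connections
    start at ``lexical_value``, since nothing about L2 word meanings can be
    inherited from the L1.

    ``mode`` sets the stratum policy: ``"sequential"`` puts the perception
    connections in stratum 1 (perception settled before recognition),
    ``"interactive"`` puts every connection in stratum 0.
    """
    pairs = tuple(pairs)
    if not pairs:
        raise ConfigurationError("at least one minimal pair is required")
    phonemic = tuple(phonemic_inventory) if phonemic_inventory is not None else l1.phonetic
    phonemic_table = np.where(
        np.asarray(l1.phonetic)[:, None] == np.asarray(phonemic)[None, :],
        float(faithful_value),
        float(unfaithful_value),
    ).astype(float)
    lexical_table = np.full((len(pairs), len(phonemic), 2), float(lexical_value))
    if mode == "sequential":
        strata = {"perception": 1, "phonemic": 0, "lexical": 0}
    elif mode == "interactive":
        strata = {"perception": 0, "phonemic": 0, "lexical": 0}
    else:
        raise ConfigurationError(f"unknown processing mode {mode!r}")
    return Grammar(
        l1.bins.copy(),
        l1.phonetic,
        l1.perception.copy(),
        phonemic=phonemic,
        phonemic_table=phonemic_table,
        pairs=pairs,
        lexical_table=lexical_table,
        strata=strata,
    )


def connection_strength_order(c1, c2) -> str:
    """Order two noise-distorted connections by dominance.

    ``c1`` and ``c2`` are ``(stratum, noisy_value)`` pairs.  A connection
    *dominates* (is the worse violation) if its stratum is higher, or — at
    equal stratum — its noisy ranking value is higher.  Returns one of
    ``"c1_dominates"``, ``"c2_dominates"``, ``"tie"``.
    """
    a, b = (c1[0], c1[1]), (c2[0], c2[1])
    if a == b:
        return "tie"
    return "c1_dominates" if a > b else "c2_dominates"
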