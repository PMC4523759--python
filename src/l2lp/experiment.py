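"""The full two-phase learning experiment and its reported metrics.

Each simulated learner is trained in two phases.  The L1 phase trains a
perception-only grammar directly on [acoustic] ~ /phonetic/ pairs from the
Dutch corpus (infants acquire perceptual warping before a lexicon exists).
The grammar is then Full-Copied into an L2 network — sequential or
interactive stratum policy — and trained on Spanish minimal-pair tokens
where the only feedback is the intended word meaning.  Held-out accuracy is
probed at checkpoints with evaluation noise on (stochastic evaluation is
intrinsic to the model, so test behavior is noisy too), and phonetic
categorization curves are probed on the full F1 grid.

The middle Dutch vowel /ɪ/ has no Spanish counterpart; the area under its
categorization curve (response proportion summed over bins × 0.1 Bark)
measures how much of the continuum it still claims.  Sequential and
interactive learners are compared on exactly this statistic.

A closed-form oracle (:func:`matching_oracle`) computes, from the
generating Gaussians, both the Bayes-optimal accuracy and the
probability-matching accuracy Σ_bins p(bin)·Σ_c p(c|bin)² — the known
stationary value of the symmetric Gradual Learning Algorithm — which is
what the trained learners' held-out accuracy should approach.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as FilePath

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corpus import (
    CorpusConfig,
    VowelDistribution,
    dutch_config,
    generate_corpus,
    sample_training_stream,
    spanish_config,
    split_train_test,
)
from .errors import ConfigurationError
from .evaluation import GrammarEvaluator, NoiseModel
from .grammar import Grammar, build_l1_grammar, default_grid, default_lexicon, full_copy_to_l2
from .learning import PlasticitySchedule, train_learner

__all__ = [
    "ExperimentConfig",
    "LearnerResult",
    "ModeComparison",
    "OracleResult",
    "ExperimentResults",
    "recognition_rate",
    "categorization_curve",
    "ih_area",
    "matching_oracle",
    "run_l1_phase",
    "run_l2_phase",
    "compare_modes",
    "run_experiment",
]

DEFAULT_CHECKPOINTS = (0, 1000, 2000, 4000, 8000, 10_000, 20_000, 40_000)
DEFAULT_CURVE_CHECKPOINTS = (2000, 10_000, 40_000)


@dataclass
class ExperimentConfig:
    """All tunables of the two-phase experiment, with the standard defaults."""

    dutch: CorpusConfig = field(default_factory=dutch_config)
    spanish: CorpusConfig = field(default_factory=spanish_config)
    initial_value: float = 100.0
    faithful_value: float = 95.0
    unfaithful_value: float = 105.0
    lexical_value: float = 100.0
    noise_sd: float = 2.0
    plasticity: PlasticitySchedule = field(default_factory=PlasticitySchedule)
    iterations: int = 40_000
    learners: int = 50
    modes: tuple[str, ...] = ("sequential", "interactive")
    checkpoints: tuple[int, ...] = DEFAULT_CHECKPOINTS
    curve_checkpoints: tuple[int, ...] = DEFAULT_CURVE_CHECKPOINTS
    probe_samples: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.learners <= 0 or self.iterations <= 0 or self.probe_samples <= 0:
            raise ConfigurationError("counts must be positive")
        if any(c < 0 or c > self.iterations for c in self.checkpoints):
            raise ConfigurationError("checkpoints must lie within [0, iterations]")
        unknown = set(self.modes) - {"sequential", "interactive"}
        if unknown:
            raise ConfigurationError(f"unknown modes {sorted(unknown)}")

    # -- serialization ------------------------------------------------- #

    def to_dict(self) -> dict:
        def corpus(c: CorpusConfig) -> dict:
            d = {
                "n_tokens": c.n_tokens,
                "train_fraction": c.train_fraction,
                "distributions": [
                    {"category": x.category, "mean": x.mean, "sd": x.sd, "weight": x.weight}
                    for x in c.distributions
                ],
            }
            if c.phase == "L2":
                d["n_synthetic_pairs"] = len(c.pairs) - 1
            return d

        return {
            "seed": self.seed,
            "learners": self.learners,
            "iterations": self.iterations,
            "modes": list(self.modes),
            "noise_sd": self.noise_sd,
            "initial_value": self.initial_value,
            "faithful_value": self.faithful_value,
            "unfaithful_value": self.unfaithful_value,
            "lexical_value": self.lexical_value,
            "plasticity": {
                "initial": self.plasticity.initial,
                "decay_factor": self.plasticity.decay_factor,
                "decay_interval": self.plasticity.decay_interval,
            },
            "checkpoints": list(self.checkpoints),
            "curve_checkpoints": list(self.curve_checkpoints),
            "probe_samples": self.probe_samples,
            "dutch": corpus(self.dutch),
            "spanish": corpus(self.spanish),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kw = dict(d)
        if "plasticity" in kw:
            kw["plasticity"] = PlasticitySchedule(**kw["plasticity"])
        for key, factory in (("dutch", dutch_config), ("spanish", spanish_config)):
            if key in kw:
                c = dict(kw[key])
                if "distributions" in c:
                    c["distributions"] = tuple(
                        VowelDistribution(**x) for x in c["distributions"]
                    )
                    if key == "dutch":
                        kw[key] = CorpusConfig("L1", c["distributions"],
                                               c.get("n_tokens", 1500),
                                               train_fraction=c.get("train_fraction", 0.9))
                    else:
                        pairs = default_lexicon(c.get("n_synthetic_pairs", 20))
                        kw[key] = CorpusConfig("L2", c["distributions"],
                                               c.get("n_tokens", 1000), pairs=pairs,
                                               train_fraction=c.get("train_fraction", 0.9))
                else:
                    n_pairs = c.pop("n_synthetic_pairs", None)
                    if n_pairs is not None:
                        c["pairs"] = default_lexicon(n_pairs)
                    kw[key] = factory(**c)
        for key in ("modes", "checkpoints", "curve_checkpoints"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False, allow_unicode=True)


@dataclass
class LearnerResult:
    """Everything recorded for one simulated learner in one processing mode."""

    learner_id: int
    mode: str
    l1_curve: list  # [(step, accuracy)]
    l2_curve: list  # [(step, accuracy)]
    categorization: pd.DataFrame  # step, bin, category, proportion
    ih_areas: dict  # step -> area (Bark)
    grammar: Grammar | None = None

    @property
    def final_l1_accuracy(self) -> float:
        return self.l1_curve[-1][1]

    @property
    def final_l2_accuracy(self) -> float:
        return self.l2_curve[-1][1]


# ---------------------------------------------------------------------- #
# probes

def recognition_rate(grammar: Grammar, tokens, noise_sd: float, rng) -> float:
    """Held-out accuracy: one noisy evaluation per token, target-level match.

    L1 tokens score the phonetic category, L2 tokens the recognized meaning.
    Never mutates the grammar.
    """
    if len(tokens) == 0:
        raise ValueError("no test tokens")
    ev = GrammarEvaluator(grammar, noise_sd)
    correct = 0
    if tokens[0].phase == "L1":
        pidx = {v: k for k, v in enumerate(grammar.phonetic)}
        for t in tokens:
            correct += ev.evaluate_l1(grammar.bin_index(t.f1_bin), rng) == pidx[t.target]
    else:
        for t in tokens:
            b = grammar.bin_index(t.f1_bin)
            pr = grammar._pair_index[t.carrier]
            _, _, m = ev.evaluate(b, pr, rng)
            correct += m == grammar.meaning_slot(t.carrier, t.target)
    return correct / len(tokens)


def categorization_curve(
    grammar: Grammar,
    bins=None,
    n_probe_samples: int = 200,
    level: str = "phonetic",
    noise_sd: float = 2.0,
    rng=None,
) -> pd.DataFrame:
    """Per-bin response proportions of each category under noisy evaluation.

    For a full grammar each probe runs a complete acoustics-to-lexicon
    evaluation with a uniformly sampled carrier pair and reports the winning
    path's unit at the requested ``level`` (``"phonetic"`` or
    ``"phonemic"``).  Proportions per bin sum to one.
    """
    if n_probe_samples < 1:
        raise ValueError("need at least one probe sample")
    rng = np.random.default_rng() if rng is None else rng
    bins = grammar.bins if bins is None else np.asarray(bins, dtype=float)
    ev = GrammarEvaluator(grammar, noise_sd)
    if level == "phonetic":
        categories = grammar.phonetic
    elif level == "phonemic":
        if not grammar.is_lexical:
            raise ConfigurationError("phonemic curves require a full grammar")
        categories = grammar.phonemic
    else:
        raise ConfigurationError(f"unknown level {level!r}")
    rows = []
    for f1 in bins:
        b = grammar.bin_index(float(f1))
        counts = np.zeros(len(categories), dtype=int)
        if grammar.is_lexical:
            pair_draws = rng.integers(len(grammar.pairs), size=n_probe_samples)
            for pr in pair_draws:
                i, j, _ = ev.evaluate(b, int(pr), rng)
                counts[i if level == "phonetic" else j] += 1
        else:
            for _ in range(n_probe_samples):
                counts[ev.evaluate_l1(b, rng)] += 1
        for cat, c in zip(categories, counts):
            rows.append((float(f1), cat, c / n_probe_samples))
    return pd.DataFrame(rows, columns=["bin", "category", "proportion"])


def ih_area(curve: pd.DataFrame, category: str = "ɪ", bin_width: float = 0.1) -> float:
    """Area under one category's categorization curve (proportion × Bark).

    With full support on the default 61-bin grid the maximum is 6.1 Bark.
    """
    if category not in set(curve["category"]):
        raise ValueError(f"category {category!r} not present in the curve")
    sub = curve[curve["category"] == category]
    return float(sub["proportion"].sum() * bin_width)


# ---------------------------------------------------------------------- #
# oracle

@dataclass(frozen=True)
class OracleResult:
    """Asymptotic accuracies implied by the generating distributions."""

    matching_accuracy: float
    bayes_accuracy: float
    boundaries: tuple[float, ...]


def matching_oracle(distributions, grid=None) -> OracleResult:
    """Bayes-optimal and probability-matching accuracy on the binned grid.

    Bin masses integrate each Gaussian between bin midpoints, with the edge
    bins absorbing the clipped tails.  ``boundaries`` are the grid points
    where the Bayes-optimal category changes.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    edges = np.concatenate([[-np.inf], (grid[:-1] + grid[1:]) / 2.0, [np.inf]])
    w = np.array([d.weight for d in distributions], dtype=float)
    w = w / w.sum()
    masses = np.array(
        [np.diff(stats.norm.cdf(edges, d.mean, d.sd)) for d in distributions]
    )  # (C, B)
    joint = w[:, None] * masses
    p_bin = joint.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_cat = np.where(p_bin > 0, joint / p_bin, 0.0)
    matching = float(np.sum(p_bin * np.sum(p_cat**2, axis=0)))
    bayes = float(np.sum(p_bin * p_cat.max(axis=0)))
    argmax = p_cat.argmax(axis=0)
    boundaries = tuple(
        float(grid[k]) for k in range(1, len(grid)) if argmax[k] != argmax[k - 1]
    )
    return OracleResult(matching, bayes, boundaries)


# ---------------------------------------------------------------------- #
# phases

def run_l1_phase(config: ExperimentConfig, rng=None):
    """Train one learner's L1 perception grammar on a fresh Dutch corpus.

    Returns the trained grammar and the held-out identification-accuracy
    curve over the configured checkpoints.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rng_corpus, rng_train, rng_probe = rng.spawn(3)
    corpus = generate_corpus(config.dutch, rng_corpus)
    train, test = split_train_test(corpus, config.dutch.train_fraction, rng_corpus)
    stream = sample_training_stream(train, config.iterations, rng_corpus)
    inventory = tuple(d.category for d in config.dutch.distributions)
    grammar = build_l1_grammar(inventory, config.dutch.grid, config.initial_value)
    noise = NoiseModel(config.noise_sd)
    curve = []

    def probe(step, g):
        curve.append((step, recognition_rate(g, test, config.noise_sd, rng_probe)))

    train_learner(grammar, stream, noise, config.plasticity,
                  checkpoints=config.checkpoints, probe=probe, rng=rng_train)
    return grammar, curve


def run_l2_phase(l1_grammar: Grammar, config: ExperimentConfig, mode: str,
                 rng=None, learner_id: int = 0, keep_grammar: bool = True) -> LearnerResult:
    """Full-copy an L1 grammar and train it on a fresh Spanish corpus.

    Records the held-out meaning-recognition curve at every checkpoint and
    phonetic categorization curves (plus the /ɪ/ area) at the curve
    checkpoints.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rng_corpus, rng_train, rng_probe, rng_curve = rng.spawn(4)
    grammar = full_copy_to_l2(
        l1_grammar, config.spanish.pairs,
        faithful_value=config.faithful_value,
        unfaithful_value=config.unfaithful_value,
        lexical_value=config.lexical_value,
        mode=mode,
    )
    corpus = generate_corpus(config.spanish, rng_corpus)
    train, test = split_train_test(corpus, config.spanish.train_fraction, rng_corpus)
    stream = sample_training_stream(train, config.iterations, rng_corpus)
    noise = NoiseModel(config.noise_sd)
    curve_steps = set(config.curve_checkpoints)
    l2_curve, curve_frames, areas = [], [], {}

    def probe(step, g):
        l2_curve.append((step, recognition_rate(g, test, config.noise_sd, rng_probe)))
        if step in curve_steps:
            cdf = categorization_curve(
                g, n_probe_samples=config.probe_samples, level="phonetic",
                noise_sd=config.noise_sd, rng=rng_curve,
            )
            cdf.insert(0, "step", step)
            curve_frames.append(cdf)
            middle = l1_grammar.phonetic[1] if len(l1_grammar.phonetic) == 3 else None
            if middle is not None:
                areas[step] = ih_area(cdf, category=middle)

    checkpoints = sorted(set(config.checkpoints) | curve_steps)
    train_learner(grammar, stream, noise, config.plasticity,
                  checkpoints=checkpoints, probe=probe, rng=rng_train)
    categorization = (
        pd.concat(curve_frames, ignore_index=True)
        if curve_frames
        else pd.DataFrame(columns=["step", "bin", "category", "proportion"])
    )
    return LearnerResult(
        learner_id, mode, [], l2_curve, categorization, areas,
        grammar=grammar if keep_grammar else None,
    )


# ---------------------------------------------------------------------- #
# mode comparison

def _welch(a, b):
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.var() == 0.0 and b.var() == 0.0:
        # degenerate variance: exact-equality shortcut
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _mean_ci(x, level=0.95):
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if len(x) < 2 or x.std(ddof=1) == 0:
        return m, m, m
    half = stats.t.ppf(0.5 + level / 2, len(x) - 1) * x.std(ddof=1) / np.sqrt(len(x))
    return m, m - half, m + half


@dataclass
class ModeComparison:
    """Sequential-vs-interactive comparison of final /ɪ/ use."""

    step: int
    category: str
    area_mean_sequential: float
    area_ci_sequential: tuple[float, float]
    area_mean_interactive: float
    area_ci_interactive: tuple[float, float]
    area_t: float
    area_p: float
    per_bin: pd.DataFrame
    significant_ranges: tuple[tuple[float, float], ...]


def compare_modes(seq_results, int_results, step: int | None = None,
                  category: str = "ɪ", alpha: float = 0.05) -> ModeComparison:
    """Welch tests on /ɪ/ areas and per-bin /ɪ/ proportions (Holm-corrected).

    The aggregate test compares per-learner areas under the /ɪ/ curve at the
    chosen checkpoint; the per-bin tests locate where on the continuum the
    two processing modes categorize differently, reported as contiguous
    significant bin ranges.
    """
    if len(seq_results) < 2 or len(int_results) < 2:
        raise ConfigurationError("need at least two learners per group")
    if step is None:
        step = max(set(seq_results[0].ih_areas) & set(int_results[0].ih_areas))

    def areas(results):
        return np.array([r.ih_areas[step] for r in results])

    def proportions(results):
        mats = []
        for r in results:
            sub = r.categorization
            sub = sub[(sub["step"] == step) & (sub["category"] == category)]
            sub = sub.sort_values("bin")
            mats.append(sub["proportion"].to_numpy())
        return np.vstack(mats), np.sort(sub["bin"].unique())

    a_seq, a_int = areas(seq_results), areas(int_results)
    t, p = _welch(a_seq, a_int)
    m_seq, lo_seq, hi_seq = _mean_ci(a_seq)
    m_int, lo_int, hi_int = _mean_ci(a_int)

    mat_seq, bins = proportions(seq_results)
    mat_int, _ = proportions(int_results)
    per = [_welch(mat_seq[:, k], mat_int[:, k]) for k in range(len(bins))]
    tvals = np.array([x[0] for x in per])
    pvals = np.array([x[1] for x in per])
    significant, p_holm, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    per_bin = pd.DataFrame({
        "bin": bins,
        "mean_sequential": mat_seq.mean(axis=0),
        "mean_interactive": mat_int.mean(axis=0),
        "t": tvals,
        "p": pvals,
        "p_holm": p_holm,
        "significant": significant,
    })
    ranges, start = [], None
    for k, sig in enumerate(significant):
        if sig and start is None:
            start = k
        if not sig and start is not None:
            ranges.append((float(bins[start]), float(bins[k - 1])))
            start = None
    if start is not None:
        ranges.append((float(bins[start]), float(bins[-1])))
    return ModeComparison(
        step, category, float(m_seq), (float(lo_seq), float(hi_seq)),
        float(m_int), (float(lo_int), float(hi_int)), t, p, per_bin, tuple(ranges),
    )


# ---------------------------------------------------------------------- #
# full experiment

@dataclass
class ExperimentResults:
    """All learners' results plus the cross-mode comparison."""

    config: ExperimentConfig
    learners: list[LearnerResult]
    comparison: ModeComparison | None = None

    def by_mode(self, mode: str):
        return [r for r in self.learners if r.mode == mode]

    def learning_curves(self) -> pd.DataFrame:
        rows = []
        for r in self.learners:
            for step, acc in r.l1_curve:
                rows.append((r.learner_id, r.mode, "L1", step, acc))
            for step, acc in r.l2_curve:
                rows.append((r.learner_id, r.mode, "L2", step, acc))
        return pd.DataFrame(rows, columns=["learner", "mode", "phase", "step", "accuracy"])

    def categorization(self) -> pd.DataFrame:
        frames = []
        for r in self.learners:
            f = r.categorization.copy()
            f.insert(0, "mode", r.mode)
            f.insert(0, "learner", r.learner_id)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def mean_final_accuracy(self, phase: str, mode: str | None = None) -> float:
        rs = self.learners if mode is None else self.by_mode(mode)
        if phase == "L1":
            # the L1 phase is shared across modes within a learner; average
            # one copy per learner id
            seen, vals = set(), []
            for r in rs:
                if r.learner_id not in seen:
                    seen.add(r.learner_id)
                    vals.append(r.final_l1_accuracy)
            return float(np.mean(vals))
        return float(np.mean([r.final_l2_accuracy for r in rs]))

    def summary(self) -> str:
        lines = ["Two-phase vowel learning experiment",
                 "=" * 37,
                 f"learners per mode : {self.config.learners}",
                 f"iterations/phase  : {self.config.iterations}",
                 f"modes             : {', '.join(self.config.modes)}",
                 f"L1 mean final identification accuracy : "
                 f"{100 * self.mean_final_accuracy('L1'):.1f}%"]
        for mode in self.config.modes:
            lines.append(
                f"L2 mean final recognition accuracy ({mode:11s}): "
                f"{100 * self.mean_final_accuracy('L2', mode):.1f}%"
            )
        c = self.comparison
        if c is not None:
            lines += [
                f"final /{c.category}/ area (sequential) : {c.area_mean_sequential:.3f} Bark "
                f"[{c.area_ci_sequential[0]:.3f}, {c.area_ci_sequential[1]:.3f}]",
                f"final /{c.category}/ area (interactive): {c.area_mean_interactive:.3f} Bark "
                f"[{c.area_ci_interactive[0]:.3f}, {c.area_ci_interactive[1]:.3f}]",
                f"Welch t = {c.area_t:.2f}, p = {c.area_p:.3g}",
                "significant bins: "
                + (", ".join(f"{lo:.1f}-{hi:.1f} Bark" for lo, hi in c.significant_ranges)
                   or "none"),
            ]
        return "\n".join(lines)

    def write(self, outdir) -> None:
        """Write the learning-curve, categorization, comparison and grammar tables."""
        out = FilePath(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.learning_curves().to_csv(out / "learning_curves.tsv", sep="\t", index=False)
        self.categorization().to_csv(out / "categorization.tsv", sep="\t", index=False)
        gdir = out / "grammars"
        gdir.mkdir(exist_ok=True)
        for r in self.learners:
            if r.grammar is not None:
                r.grammar.dump(gdir / f"{r.mode}_{r.learner_id:03d}.tsv")
        summary = {
            "l1_mean_final_accuracy": self.mean_final_accuracy("L1"),
            "l2_mean_final_accuracy": {
                mode: self.mean_final_accuracy("L2", mode) for mode in self.config.modes
            },
        }
        if self.comparison is not None:
            c = self.comparison
            c.per_bin.to_csv(out / "comparison.tsv", sep="\t", index=False)
            summary["ih_area"] = {
                "step": c.step,
                "sequential_mean": c.area_mean_sequential,
                "interactive_mean": c.area_mean_interactive,
                "welch_t": c.area_t,
                "welch_p": c.area_p,
                "significant_ranges": list(c.significant_ranges),
            }
        else:
            pd.DataFrame(
                columns=["bin", "mean_sequential", "mean_interactive", "t", "p",
                         "p_holm", "significant"]
            ).to_csv(out / "comparison.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)


def run_experiment(config: ExperimentConfig, outdir=None, seed: int | None = None,
                   keep_grammars: bool = True, progress=None) -> ExperimentResults:
    """Run the full multi-learner, multi-mode experiment.

    Per learner: a fresh Dutch corpus draw and split, one L1 phase, then an
    independent Full Copy and L2 phase per processing mode (L1 behavior does
    not depend on the mode, so the trained L1 grammar is shared across the
    mode variants of a learner).  Deterministic given the master seed.
    """
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    learner_seeds = ss.spawn(config.learners)
    results: list[LearnerResult] = []
    for lid in range(config.learners):
        children = learner_seeds[lid].spawn(1 + len(config.modes))
        l1_grammar, l1_curve = run_l1_phase(config, np.random.default_rng(children[0]))
        for k, mode in enumerate(config.modes):
            r = run_l2_phase(
                l1_grammar, config, mode,
                rng=np.random.default_rng(children[1 + k]),
                learner_id=lid, keep_grammar=keep_grammars,
            )
            r.l1_curve = list(l1_curve)
            results.append(r)
        if progress is not None:
            progress(lid + 1, config.learners)
    comparison = None
    if {"sequential", "interactive"} <= set(config.modes):
        seq = [r for r in results if r.mode == "sequential"]
        inter = [r for r in results if r.mode == "interactive"]
        if len(seq) >= 2 and seq[0].ih_areas:
            comparison = compare_modes(seq, inter)
    out = ExperimentResults(config, results, comparison)
    if outdir is not None:
        out.write(outdir)
    return out
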