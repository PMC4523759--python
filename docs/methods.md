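# Methods

## The model

The simulator implements a four-level connection network for spoken-word
perception and recognition:

    [acoustic] → /phonetic/ → |phonemic| → <lexical>

The acoustic level is a discretized F1 (first-formant) continuum: 61 bins
from 2.0 to 8.0 Bark in 0.1-Bark steps.  The phonetic level holds
language-specific vowel categories, the phonemic level canonical word-form
vowels, and the lexical level word meanings.  Units are fixed; all knowledge
lives in weighted connections between adjacent levels.

A connection's **ranking value** is the penalty rank of a negative
constraint against using that mapping, so *lower value = stronger
connection*.  Evaluation is stochastic (stochastic Optimality Theory):
before each evaluation event every connection receives an independent
zero-mean Gaussian distortion (sd 2.0 by default), and a connection shared
by several candidate paths keeps one noisy value within the event.  A path
is as strong as its weakest link: candidates are compared by their worst
(most dominant) violation, ties resolved lexicographically down the sorted
violation profile — never by summing.  Exact profile ties, a measure-zero
event under continuous noise, are broken uniformly at random so that
zero-noise runs are well defined.

Each connection also carries a **stratum** index (0 or 1 here); a
connection in a higher stratum dominates every connection in a lower one
regardless of noisy values.  Placing the acoustic→phonetic connections in
stratum 1 makes processing *sequential*: the phonetic decision is settled by
perception alone and screens off all lexical evidence.  A single shared
stratum makes processing *interactive*: lexical connections can outrank
perception connections and feed back into the phonetic outcome.  This
one-bit policy is the only difference between the two learner types.

## Learning

Learning is error-driven (Gradual Learning Algorithm) and meaning-driven:
the learner observes only the intended unit at the topmost trained level —
the phonetic category during first-language (L1) training, the word meaning
during second-language (L2) training — never the intermediate
representations.  On a correct response nothing changes.  On an error the
learner re-applies fresh evaluation noise (Jarosz-style resampling) and
finds the *interpretive parse*: the optimal path among the candidates
consistent with the intended target (9 of the 18 paths in the standard
network).  Every connection on the erroneous winning path is weakened
(+plasticity on its ranking value) and every connection on the parse
strengthened (−plasticity); connections on both paths net a bit-exact zero.
Plasticity starts at 0.1 and shrinks by a factor 0.7 every 10,000 tokens,
applied discretely at multiples of the interval.

A single `update_sign` flag flips the update direction for sensitivity
analysis; flipping it demonstrably prevents learning (see the test suite).

## The subset scenario experiment

The standard experiment models native Dutch listeners — three front vowels
/i, ɪ, ɛ/ on the F1 continuum — learning the two-vowel Spanish contrast
/i, e/ from minimal pairs (e.g. *chica* "girl" / *checa* "Czech.F"), where
word meaning is the only feedback.  Per simulated learner:

1. **L1 phase.**  A perception-only grammar (all 183 acoustic→phonetic
   values initialized to 100) is trained on 40,000 tokens resampled from a
   fresh Dutch corpus (90% train / 10% held out).
2. **Full Copying.**  The trained perception table is copied verbatim into
   an L2 network.  Phonetic→phonemic connections start at 95 where the
   labels match ("faithful") and 105 elsewhere — a quantitative bias that
   learning may erode — and all phonemic→lexical connections start at 100.
   Strata are assigned per processing mode.
3. **L2 phase.**  40,000 Spanish minimal-pair tokens (again 90/10 split),
   meaning feedback only.

Fifty learners are simulated per processing mode; each learner draws its
own corpora and splits, giving honest between-learner variance.  The two
mode variants of a learner share the learner's trained L1 grammar (L1
behavior cannot depend on the stratum policy, which only matters once the
lexicon exists) and start from independent full copies of it.

Held-out accuracy is probed at checkpoints with evaluation noise on —
stochastic evaluation is intrinsic to the model, so test behavior is noisy
too — one noisy evaluation per held-out token.  Phonetic categorization
curves are probed over the whole grid (200 noisy full-path evaluations per
bin, carrier pairs sampled uniformly).  Probes draw from their own RNG
streams and never mutate the grammar.  The **/ɪ/ area** — the middle
vowel's response proportion summed over bins × 0.1 Bark, maximum 6.1 — is
the headline statistic of the sequential/interactive contrast; groups are
compared by a Welch test on per-learner areas plus per-bin Welch tests with
Holm correction (α = 0.05), reported as contiguous significant-bin ranges.
The test brand is a package choice; the effect direction is the claim.

## Synthetic corpora

Vowel categories are Gaussians over F1 in Bark, binned to the grid (round
to nearest 0.1, ties away from zero, out-of-range samples clipped to the
edges — edge mass is negligible under the defaults).  Defaults, emulating
female production data for these vowels:

| phase   | category | mean (Bark) | sd (Bark) | tokens |
|---------|----------|------------:|----------:|-------:|
| Dutch   | /i/      | 3.0         | 0.55      | 500    |
| Dutch   | /ɪ/      | 4.3         | 0.55      | 500    |
| Dutch   | /ɛ/      | 5.7         | 0.55      | 500    |
| Spanish | /i/      | 3.5         | 0.60      | 500    |
| Spanish | /e/      | 5.0         | 0.60      | 500    |

L2 tokens carry a uniformly drawn carrier from a lexicon of 21 minimal
pairs (*chica*/*checa* plus 20 schematic pairs; configurable) and the
meaning congruent with the generating category.  User-supplied token tables
are accepted as delimited text, with Hz values converted by Traunmüller's
(1990) closed form z = 26.81·f/(1960+f) − 0.53 and binned on load.

What the generator does *not* emulate: multiple cues (F2, duration),
speaker and context variation, token-frequency structure, or the exact
distributions of any recorded corpus.  Passing tests therefore show that
the learning dynamics behave as the model predicts under clean
Gaussian-mixture input, not that the simulator reproduces any particular
empirical dataset.

## The probability-matching oracle

Before interpreting trained accuracies, the package computes two
closed-form references from the generating Gaussians on the binned grid:
the Bayes-optimal accuracy Σ_b p(b)·max_c p(c|b) and the
probability-matching accuracy Σ_b p(b)·Σ_c p(c|b)², the known stationary
value of the symmetric GLA.  Under the defaults these are 85.3% / 78.8%
(Dutch three-way) and 89.4% / 84.6% (Spanish two-way).

The single-level L1 learner attains its matching value almost exactly
(50-learner mean ≈ 77–78%, the ~1-point shortfall coming from rarely
trained edge bins that remain at the uniform prior).  The multi-level L2
learner stabilizes around 79–80% recognition in both modes — measurably
*below* its 84.6% matching bound.  This is a structural property, not a
convergence artifact: runs four times longer do not raise it, while a
zero-overlap corpus drives recognition to 100%.  Two paths that share their
perception and phonemic links differ only in one lexical connection, so
per-bin meaning accuracy is capped by the margins of connections *shared*
across bins; GLA rate-balance pins those margins where aggregate error
flows cancel, and the irreducible confusion mass at the category overlap
keeps them moderate (≈5 ranking units, i.e. a ≈96% per-bin ceiling at
high-certainty bins).  The gap between a multi-level learner's asymptote
and its single-stage matching bound grows with category overlap; with less
overlapping input distributions the two coincide.  Users comparing
recognition rates against the oracle should keep this in mind.

## Numerical and design choices

- **Polarity.**  Lower ranking value = stronger connection is the single
  global convention; it is what makes the faithful 95 initialization a bias
  *toward* faithful mappings.  All update directions follow from it.
- **Noise economy.**  The training loop draws Gaussian noise only for the
  ≤18 connections reachable from the current input; unreachable connections
  cannot influence the winner or the update, so outcomes are distributed
  identically to distorting the whole grammar (the full-grammar view is
  available and is what the equivalence tests use).
- **RNG discipline.**  One master seed; per-learner seeds are spawned from
  it, and each learner splits independent substreams for corpus
  sampling/splitting, evaluation noise, parse resampling, and probes.
  Identical master seeds give bit-identical output tables.
- **Degenerate inputs.**  Empty inventories, duplicate pair ids, mixed-phase
  token streams, off-grid bins and unknown carriers raise configuration or
  lookup errors; zero evaluation noise is allowed and makes evaluation a
  pure function up to explicit uniform tie-breaks; Welch tests fall back to
  an exact-equality shortcut when both groups have zero variance.
- **Grammar serialization** round-trips every ranking value via `repr`, so
  restore is bit-exact; minimal-pair word-form labels (which play no
  computational role) are regenerated from pair ids.
- **Problem sizes.**  The full experiment (50 learners × 2 modes × 2×40,000
  tokens plus probes) runs in a few minutes on one core.  Unit and property
  tests use reduced sizes (hundreds of tokens, thousands of steps) chosen so
  that each assertion's Monte-Carlo error is well below its tolerance.

## Known limitations

- Single acoustic cue (F1); no production direction; no category creation
  (the reverse, two-to-three-vowel scenario is out of scope).
- The L1 grammar is frozen after its phase; attrition is not modeled.
- Only two strata are supported, matching the sequential/interactive
  contrast; deeper stratum hierarchies are not.
- The per-bin mode comparison is over-powered at 50 learners per group:
  Holm-corrected Welch tests flag bins whose response difference is real
  but tiny (e.g. 0.02 vs 0.00), including never-trained edge bins where
  sequential learners keep the uniform prior while interactive learners'
  shared phonemic-row disuse removes /ɪ/ globally.  The significant set can
  therefore extend beyond one compact central band under generators whose
  support does not cover the full grid.
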