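# Methods

This note documents the models implemented in `actiongram`, the numerical
and design choices behind them, what the synthetic-data generators do and
do not emulate, and the problem sizes the automated checks run at.

## Input model

The unit of analysis is a `SymbolSequence`: an ordered string of terminal
codes from a closed, ordered `EventAlphabet`.  Ethogram CSVs (sequence id,
category, code, onset, duration) are onset-sorted (stable sort, so file
order breaks ties) and projected to symbols; all timing is discarded, so
every downstream quantity is time-scale invariant.  The default alphabet
is the seven elementary knapping actions; an alias table maps
non-canonical input codes (e.g. a separate light-percussion code) onto
canonical ones before validation, and unknown codes are a hard error.
`collapse_runs` replaces maximal runs of one code by a single occurrence —
the control analysis for asking whether a corpus contrast is driven purely
by long repeated runs of a single action.

## Categorical HMM and order selection

States S, alphabet size M.  Free parameters p = S(S−1) + S(M−1) + (S−1);
the initial distribution is counted because it is estimated.  Fitting is
Baum–Welch with per-step (Rabiner) scaling over all sequences jointly
(sufficient statistics summed across sequences), implemented as numba
kernels.  EM stops when the absolute log-likelihood improvement falls
below `tol = 1e-6` or after 500 iterations.  The per-iteration
log-likelihood is checked to be non-decreasing (tolerance 1e-6) and a
violation raises — it would indicate a numerics bug, not a data property.

Initialization matters enormously for these likelihood surfaces, so each
fit is the best of `n_restarts` independent restarts; initial, transition
and emission rows are drawn from a symmetric Dirichlet(1), with one master
seed spawning per-restart seeds.  The CLI default is 1000 restarts; the
automated checks use 10–100 (see "Problem sizes" below).

Order selection: every S in a contiguous range (default 1–12) is fitted
and the argmin-BIC order chosen, ties going to the smaller S.  The BIC
sample size n is the total number of emitted symbols in the corpus — the
observations are the emissions.  (Per-sequence n would shift absolute BIC
but rarely the argmin in well-separated cases; the choice is recorded
here, not silently varied.)

Scoring and decoding floor emission probabilities at 1e-10 so symbols
absent from a state's training support remain finitely scoreable.  A
symbol with zero mass in *every* state of a model is an error — except in
cross-model uses (classification, ΔAIC covariates), where a symbol merely
unseen by one category's training corpus is carried by the floor, and only
a symbol impossible under *all* candidate models errors.  Viterbi breaks
ties toward the lower state index at every backtrack step, so decoded
paths are fully deterministic.  State labels are arbitrary across runs;
cross-run comparisons go through Hungarian matching on per-row
total-variation distance of emission matrices (`match_states`), never raw
indices.

## States-of-states (SoS)

Viterbi paths of *all* sequences, decoded under one shared model (by
convention the selected model of the more complex category, so both
categories are expressed in the same state vocabulary), are treated as a
new symbol stream over the state alphabet, and a 2-state HMM is fitted
with the same restart protocol.  Decoded SoS paths yield per-category
occupancy fractions (summing to 1 per category) and mean switch counts.
A corpus whose paths oscillate between both SoS regimes expresses one more
level of organisation than one that stays in a single regime.  Constant
input paths do not fail but flag the result degenerate.  The SoS fit is
only meaningful on the combined corpus: fitted alone, a single-regime
category's 2-state model can split that one regime across both SoS states.
`running_sos_average` (centered moving mean of the binary SoS indicator,
default window 9 events, odd, truncated at edges) is the standard display
of regime oscillation over a sequence.

## k-Sequitur

Rule creation requires a digram (adjacent element pair) to occur k times;
k = 2 is classic Sequitur behaviour, larger k makes rule discovery robust
to infrequent pairs in noisy behavior.  The implementation is a batch
fixpoint:

1. Count non-overlapping occurrences of every digram, leftmost-greedy
   within each string (so "aaa" counts one "aa"), across the top-level
   string(s) and all rule expansions.
2. If any digram has count ≥ k, create a rule for the most frequent one
   (ties: earliest first occurrence) and substitute it at all
   non-overlapping occurrences everywhere.
3. Enforce rule utility: any rule referenced fewer than twice is inlined
   at its single use site and deleted.  (The utility threshold stays 2
   for all k — the variant modifies rule creation, not deletion.)
4. Repeat until no digram reaches k.

Each substitution with count c removes c−2 ≥ 0 elements from the total
grammar size and inlining strictly shrinks it, so the procedure
terminates.  Induction is lossless by construction and property-tested:
expanding the root always reproduces the input exactly.  Rule names are
`r<n>` in creation order (transient rules leave gaps); equality of
grammars is judged by expansions, never names.  Rule levels: terminals are
level 1, a rule is one above the deepest element of its expansion, and the
root is not a rule — so a rule over terminals only is level 2.

Corpus-level induction keeps each sequence as its own top-level string:
digram counts pool across the corpus but no digram — hence no rule — ever
spans a sequence boundary, which would be an artifact of concatenation.
Per-sequence parses under the shared rule set are retained.

*Exclusive rules*: a rule belongs to a category when any parse of that
category references it, directly or through a containing rule
(reachability; direct-only counting is available as an option).  Rules
referenced by exactly one category are exclusive, counted per level.  On
noisy corpora, low k produces chance low-support exclusive rules in either
category (the spurious-rule problem that motivates k in the first place);
exclusivity analyses of the synthetic corpora therefore run at the
noise-robust end of the validated threshold ladder (k = 8), while k = 2
remains the default elsewhere.  `spurious_rules` flags rules used fewer
than 3 times.

*Compression statistics*: pre-length is the terminal count, post-length
the element count of the parse string (rules + terminals), ratio
post/pre ∈ (0, 1].  Shannon entropy H = −Σ f log₂ f is computed on the
terminal string (pre) and on the parse string (post), whose element types
are terminals and rule ids; normalized entropy divides by log₂ of the
number of distinct types present in that same string (defined as 0 for a
single type).  Across a corpus, ordinary least squares (with intercept —
forcing the line through zero would bias the slope) of post on pre length
gives slope, R², and the compression rate 1/slope.

## Complexity covariates

For short stimulus sequences, `hmm_covariate` returns
AIC(complex model) − AIC(simple model), each AIC using that model's
forward log-likelihood on the stimulus and its full parameter count (AIC
rather than BIC because stimulus length is short and variable and AIC's
penalty does not depend on sample size; p may exceed the symbol count —
sequences shorter than 10 symbols are flagged in the export).  More
negative means more complex-like; the measure is antisymmetric under model
swap.  `cfg_covariate` parses the stimulus greedily against the corpus
rule set — longest expansion first, left-to-right, unmatched spans staying
terminal, so every sequence parses and expands back exactly — and returns
the compression ratio.  Greedy parsing is deterministic and near-optimal
for hierarchical Sequitur rule sets; exhaustive optimal parsing was not
implemented because the greedy parse already attains the rule expansions'
full lengths on the corpora of interest.  Covariates export as a CSV
(sequence id, category, ΔAIC, CFG ratio, short-sequence flag); duplicate
ids are an error.

## Synthetic generators

`generate_oldowan_like` emulates simple flake production: each sequence
concatenates flake-removal chunks — 1–3 context events drawn from a fixed
mixture (T 0.6, G 0.25, H 0.15), a detaching percussion run of 1–3 P, a
flake detach F, and a rare tool change X (p = 0.05) — to a target length
drawn uniformly from 80–300 symbols (chunks are appended whole, so lengths
can overshoot by one chunk).  Percussion runs never exceed 3 and the
inversion code I never occurs.

`generate_acheulean_like` uses the same chunk grammar over lengths
200–800, but with probability `prep_prob = 0.5` a chunk embeds a
platform-preparation insert before the detaching strike: 1–3 alternating
inversion/target events (I-led), each followed by a run of 5–12 repeated
P.  The inserts are what make these corpora different: they add
emission-distinct states (long-run percussion, inversion-led context),
long compressible runs, and a second temporal regime.

Drawing context symbols from a mixture rather than in a fixed order is
deliberate: one hidden regime can emit the mixture (keeping the optimal
HMM order low), while the random draws break exact digram repetition
between chunks (keeping the simple corpus from over-compressing).  The
chunk parameters were calibrated once so that a 9-vs-8 corpus reproduces
the qualitative battery — BIC order 4 vs 6, single-SoS vs oscillating SoS,
smaller slope / larger compression rate for the complex corpus, lower
pre- and higher post-compression entropy, and complex-category-only
exclusive rules — and are not varied per test.

What the generators do *not* emulate: event timing and durations,
kinematics, raw-material contingency, inter-individual variation, and the
drift of real sequences toward exhaustion of the core.  Passing the
synthetic battery shows the pipeline detects the intended structural
contrasts at realistic sizes; it does not certify effect sizes on real
behavioral data.

## Problem sizes in the automated checks

Simulation-based tests run at sizes chosen to exercise the statistics,
not the full field protocol: restart counts of 10–100 (the CLI default
stays 1000), order scans over S = 1–8, planted-model recovery with 20
replicate corpora of 10 × 150 symbols, and the synthetic contrast on the
9-vs-8 corpus above with 20 restarts per order.  Oracle tests compare
forward/Viterbi against exhaustive path enumeration at S ≤ 4, length ≤ 8,
within 1e-8 in log space, and hmmlearn serves as an independent
cross-check of forward scoring.  The deposited-corpus reproduction
requires a locally supplied copy of the archived data
(`data/deposited/sequences.txt`); it is not redistributable here, and the
corresponding tests report the missing file rather than silently skipping.

## Known limitations

- The batch most-frequent-digram formulation of k-Sequitur is one
  deterministic member of the family of digram-substitution grammars; at
  k = 2 it reproduces the canonical examples but is not guaranteed to
  emit byte-identical grammars to the online linked-list algorithm on all
  inputs (grammar equality is by expansion, and all structural invariants
  hold for both).
- BIC order selection inherits restart stochasticity: with few restarts
  the selected order can fluctuate by ±1 on weakly separated corpora.
- Greedy corpus parsing for the CFG covariate is not guaranteed optimal
  for adversarial rule sets.
- The SoS model is exactly 2-state by design; deeper hierarchies would
  need repeated application.
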