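"""Synthetic knapping-like corpora with controlled structural complexity.

Two generators emulate the structure that separates early (Oldowan-like)
from late (Acheulean-like) Lower Paleolithic tool-making sequences:

* *Oldowan-like* sequences repeat one simple flake-removal chunk —
  a short context phase (target change, grip shifts) followed by one or
  two percussion strikes and a flake detachment.  Percussion runs never
  exceed length 3.
* *Acheulean-like* sequences are built from the same chunks, but with
  probability ``prep_prob`` a chunk embeds a platform-preparation insert:
  alternating target changes/inversions, each followed by a long run
  (>= 5) of repeated percussion, before the detaching strike.

The inserts give Acheulean-like corpora a strictly higher optimal HMM
order, two-regime states-of-states structure, and far more rule-based
compressibility — the qualitative contrasts the analysis pipeline is
designed to detect.  Timing, kinematics and raw-material realism are
not modeled; only the symbolic structure is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ethogram_io import DEFAULT_ALPHABET, EventAlphabet, SymbolSequence
from .hmm_grammar import HmmModel

__all__ = [
    "GeneratorSpec",
    "OLDOWAN_SPEC",
    "ACHEULEAN_SPEC",
    "sample_from_hmm",
    "generate_chunked",
    "generate_oldowan_like",
    "generate_acheulean_like",
    "well_separated_hmm",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one chunk-grammar corpus generator."""

    category: str
    length_range: tuple[int, int]            # min/max symbols per sequence
    prep_prob: float = 0.0                   # platform-prep insert per chunk
    prep_run_range: tuple[int, int] = (5, 12)   # repeated-P run length
    prep_alternations: tuple[int, int] = (1, 3)  # T/I alternations per insert
    strike_range: tuple[int, int] = (1, 3)   # detaching percussion run
    tool_change_prob: float = 0.05
    generator_hmm: HmmModel | None = None

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid length_range")
        if not 0.0 <= self.prep_prob <= 1.0:
            raise ValueError("prep_prob must be a probability")
        if self.prep_run_range[0] < 5:
            raise ValueError("platform-prep percussion runs must be >= 5")


#: Study-condition defaults: 9 short simple sequences vs 8 longer complex
#: ones, mirroring the 9-vs-8 Oldowan/Acheulean design.
OLDOWAN_SPEC = GeneratorSpec(category="Oldowan", length_range=(80, 300))
ACHEULEAN_SPEC = GeneratorSpec(category="Acheulean", length_range=(200, 800),
                               prep_prob=0.5)


def sample_from_hmm(model: HmmModel, length: int, seed: int = 0,
                    sequence_id: str = "sim", category: str = "") -> SymbolSequence:
    """Ancestral sampling of one sequence from a categorical HMM."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    S = model.n_states
    codes = model.alphabet.codes
    states = np.empty(length, dtype=np.int64)
    states[0] = rng.choice(S, p=model.initial)
    for t in range(1, length):
        states[t] = rng.choice(S, p=model.transition[states[t - 1]])
    symbols = tuple(codes[rng.choice(len(codes), p=model.emission[s])]
                    for s in states)
    return SymbolSequence(sequence_id=sequence_id, category=category,
                          symbols=symbols)


#: Context-phase emission mixture: mostly target changes, some grip work.
_CTX_SYMBOLS = ("T", "G", "H")
_CTX_PROBS = (0.6, 0.25, 0.15)


def _chunk(rng: np.random.Generator, spec: GeneratorSpec) -> list[str]:
    """One flake-removal chunk, optionally with a platform-prep insert.

    Context symbols are drawn from a fixed mixture rather than in a fixed
    order: a single hidden regime can emit them, but the draws break
    exact digram repetition between chunks.
    """
    n_ctx = 1 + int(rng.random() < 0.5) + int(rng.random() < 0.25)
    out: list[str] = [str(rng.choice(_CTX_SYMBOLS, p=_CTX_PROBS)) for _ in range(n_ctx)]
    if spec.prep_prob > 0 and rng.random() < spec.prep_prob:
        n_alt = int(rng.integers(spec.prep_alternations[0],
                                 spec.prep_alternations[1] + 1))
        for j in range(n_alt):
            out.append("I" if j % 2 == 0 else "T")
            run = int(rng.integers(spec.prep_run_range[0],
                                   spec.prep_run_range[1] + 1))
            out.extend(["P"] * run)
    out.extend(["P"] * int(rng.integers(spec.strike_range[0],
                                        spec.strike_range[1] + 1)))
    out.append("F")
    if rng.random() < spec.tool_change_prob:
        out.append("X")
    return out


def generate_chunked(spec: GeneratorSpec, n: int, seed: int = 0,
                     id_prefix: str | None = None) -> list[SymbolSequence]:
    """Generate ``n`` sequences by concatenating chunks to a target length.

    Target lengths are uniform integers over ``spec.length_range``;
    chunks are appended whole, so actual lengths may overshoot by at most
    one chunk.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    prefix = id_prefix or spec.category.lower() or "sim"
    out = []
    for i in range(n):
        target = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        symbols: list[str] = []
        while len(symbols) < target:
            symbols.extend(_chunk(rng, spec))
        out.append(SymbolSequence(sequence_id=f"{prefix}{i + 1}",
                                  category=spec.category,
                                  symbols=tuple(symbols)))
    return out


def generate_oldowan_like(n: int, seed: int = 0,
                          spec: GeneratorSpec = OLDOWAN_SPEC) -> list[SymbolSequence]:
    """Corpus of simple flake-removal sequences (no long percussion runs)."""
    return generate_chunked(spec, n, seed=seed)


def generate_acheulean_like(n: int, seed: int = 0, prep_prob: float | None = None,
                            spec: GeneratorSpec = ACHEULEAN_SPEC) -> list[SymbolSequence]:
    """Corpus of shaping-like sequences with platform-preparation inserts.

    ``prep_prob`` overrides the per-chunk insert probability; 0 reduces
    the generator to the Oldowan-like chunk grammar (over the Acheulean
    length range).
    """
    if prep_prob is not None:
        spec = GeneratorSpec(**{**spec.__dict__, "prep_prob": prep_prob})
    return generate_chunked(spec, n, seed=seed)


def well_separated_hmm(n_states: int, alphabet: EventAlphabet = DEFAULT_ALPHABET,
                       self_loop: float = 0.8, purity: float = 0.95,
                       seed: int = 0) -> HmmModel:
    """Planted HMM with near-disjoint emissions for recovery experiments.

    Each state emits one dedicated symbol with probability ``purity`` and
    the remainder uniformly; transitions are a noisy cycle with
    ``self_loop`` mass on staying put.  Requires n_states <= alphabet size.
    """
    M = len(alphabet)
    if n_states > M:
        raise ValueError("need at least one dedicated symbol per state")
    rng = np.random.default_rng(seed)
    own = rng.permutation(M)[:n_states]
    B = np.full((n_states, M), (1.0 - purity) / (M - 1))
    B[np.arange(n_states), own] = purity
    A = np.full((n_states, n_states), 0.0)
    for i in range(n_states):
        A[i, i] = self_loop
        A[i, (i + 1) % n_states] = 1.0 - self_loop
    if n_states == 1:
        A[0, 0] = 1.0
    pi = np.full(n_states, 1.0 / n_states)
    return HmmModel(alphabet=alphabet, initial=pi, transition=A, emission=B)
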