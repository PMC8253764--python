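"""Deterministic context-free grammar induction by k-Sequitur.

Classic Sequitur builds a hierarchical grammar by replacing any symbol
digram (adjacent pair) that occurs twice with a new rule, subject to rule
utility (a rule referenced fewer than twice is inlined and deleted).  On
noisy behavioral sequences this creates many spurious low-support rules,
so the variant implemented here, *k-Sequitur*, requires a digram to occur
k times (non-overlapping) before a rule is created; k = 2 recovers the
classic behavior.

Induction is run as a batch fixpoint: count non-overlapping leftmost
occurrences of every digram across the root string(s) and all rule
expansions, substitute the most frequent digram with count >= k
everywhere, enforce rule utility, and repeat until no digram reaches k.
Compression is lossless — expanding the root reproduces the input
exactly — and the grammar's size and entropy statistics quantify the
rule-based structure of a corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .ethogram_io import SymbolSequence

__all__ = [
    "RuleRef",
    "Rule",
    "Grammar",
    "CorpusGrammar",
    "CompressionResult",
    "CorpusCompression",
    "k_sequitur",
    "expand",
    "rule_levels",
    "spurious_rules",
    "fit_corpus",
    "exclusive_rules",
    "shannon_entropy",
    "normalized_entropy",
    "compress_stats",
    "compress_corpus",
    "compression_regression",
    "format_grammar",
    "grammar_to_json",
    "grammar_from_json",
    "KSequitur",
]


@dataclass(frozen=True)
class RuleRef:
    """Reference to a non-terminal; distinct from any terminal token."""

    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Rule:
    expansion: tuple  # of str | RuleRef
    usage_count: int
    level: int


@dataclass(frozen=True)
class Grammar:
    """k-Sequitur output for one sequence: root string plus rule table."""

    k: int
    root: tuple  # of str | RuleRef
    rules: dict[str, Rule]
    sequence_id: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass(frozen=True)
class CorpusGrammar:
    """One shared rule set induced jointly over a corpus.

    Sequences never share digrams across their boundaries (each sequence
    is a separate top-level string during induction), so no rule spans two
    sequences; ``parses`` holds each sequence's compressed top-level
    string under the shared rules.
    """

    k: int
    rules: dict[str, Rule]
    parses: tuple  # of (sequence_id, category, tuple-of-elements)

    def parse_of(self, sequence_id: str) -> tuple:
        for sid, _, parse in self.parses:
            if sid == sequence_id:
                return parse
        raise KeyError(sequence_id)

    def as_grammar(self, sequence_id: str) -> Grammar:
        """Single-sequence view sharing the corpus rule table."""
        for sid, cat, parse in self.parses:
            if sid == sequence_id:
                return Grammar(k=self.k, root=parse, rules=self.rules,
                               sequence_id=sid, category=cat)
        raise KeyError(sequence_id)


# ---------------------------------------------------------------------------
# induction engine
# ---------------------------------------------------------------------------

def _count_digrams(strings: list[list]) -> dict:
    """Non-overlapping, leftmost-greedy digram counts across all strings.

    Returns digram -> (count, first_occurrence_key); the key orders
    digrams by first appearance for deterministic tie-breaking.
    """
    counts: dict = {}
    for si, s in enumerate(strings):
        last_end: dict = {}
        for i in range(len(s) - 1):
            d = (s[i], s[i + 1])
            if last_end.get(d, -1) > i:
                continue  # overlaps the previous counted occurrence
            last_end[d] = i + 2
            if d in counts:
                counts[d][0] += 1
            else:
                counts[d] = [1, (si, i)]
    return counts


def _substitute(s: list, d: tuple, ref: RuleRef) -> list:
    """Replace non-overlapping leftmost occurrences of digram ``d``."""
    out: list = []
    i = 0
    n = len(s)
    while i < n:
        if i + 1 < n and s[i] == d[0] and s[i + 1] == d[1]:
            out.append(ref)
            i += 2
        else:
            out.append(s[i])
            i += 1
    return out


def _usage_counts(strings: list[list], expansions: dict[str, list]) -> dict[str, int]:
    usage = {name: 0 for name in expansions}
    for s in strings:
        for el in s:
            if isinstance(el, RuleRef):
                usage[el.name] += 1
    for exp in expansions.values():
        for el in exp:
            if isinstance(el, RuleRef):
                usage[el.name] += 1
    return usage


def _inline_once(strings: list[list], expansions: dict[str, list], name: str) -> None:
    ref = RuleRef(name)
    exp = expansions.pop(name)

    def repl(s: list) -> list:
        out: list = []
        for el in s:
            if el == ref:
                out.extend(exp)
            else:
                out.append(el)
        return out

    for i, s in enumerate(strings):
        strings[i] = repl(s)
    for n2 in list(expansions):
        expansions[n2] = repl(expansions[n2])


def _induce(token_strings: list[list[str]], k: int):
    """Run k-Sequitur over one or more top-level strings.

    Returns (top_strings, expansions, usage).  Rule names are ``r<n>`` in
    creation order; transient rules removed by utility leave gaps, so
    names carry no meaning beyond identity.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    strings: list[list] = [list(s) for s in token_strings]
    expansions: dict[str, list] = {}
    counter = 0

    while True:
        counts = _count_digrams(strings + list(expansions.values()))
        candidates = [(c, key, d) for d, (c, key) in counts.items() if c >= k]
        if not candidates:
            break
        # most frequent digram; ties to the earliest first occurrence
        candidates.sort(key=lambda t: (-t[0], t[1]))
        _, _, d = candidates[0]
        counter += 1
        name = f"r{counter}"
        ref = RuleRef(name)
        for i, s in enumerate(strings):
            strings[i] = _substitute(s, d, ref)
        for n2 in list(expansions):
            expansions[n2] = _substitute(expansions[n2], d, ref)
        expansions[name] = list(d)
        # rule utility: inline anything referenced fewer than twice
        while True:
            usage = _usage_counts(strings, expansions)
            weak = [n2 for n2, u in usage.items() if u < 2]
            if not weak:
                break
            _inline_once(strings, expansions, weak[0])

    usage = _usage_counts(strings, expansions)
    return strings, expansions, usage


def _levels(expansions: Mapping[str, Sequence]) -> dict[str, int]:
    levels: dict[str, int] = {}
    visiting: set[str] = set()

    def level_of(el) -> int:
        if not isinstance(el, RuleRef):
            return 1
        name = el.name
        if name in levels:
            return levels[name]
        if name in visiting:
            raise ValueError(f"cycle through rule {name}")
        if name not in expansions:
            raise ValueError(f"dangling rule reference {name}")
        visiting.add(name)
        lv = 1 + max(level_of(e) for e in expansions[name])
        visiting.discard(name)
        levels[name] = lv
        return lv

    for name in expansions:
        level_of(RuleRef(name))
    return levels


def _build_rules(expansions: Mapping[str, list], usage: Mapping[str, int]) -> dict[str, Rule]:
    lv = _levels(expansions)
    return {
        name: Rule(expansion=tuple(exp), usage_count=usage[name], level=lv[name])
        for name, exp in expansions.items()
    }


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def k_sequitur(seq: SymbolSequence, k: int = 2) -> Grammar:
    """Induce a deterministic CFG from one sequence.

    A sequence of length < 2 yields a rule-free grammar whose root is the
    input itself.
    """
    if len(seq) < 2:
        return Grammar(k=k, root=tuple(seq.symbols), rules={},
                       sequence_id=seq.sequence_id, category=seq.category)
    strings, expansions, usage = _induce([list(seq.symbols)], k)
    return Grammar(
        k=k,
        root=tuple(strings[0]),
        rules=_build_rules(expansions, usage),
        sequence_id=seq.sequence_id,
        category=seq.category,
    )


def _expand_elements(elements: Sequence, rules: Mapping[str, Rule]) -> list[str]:
    out: list[str] = []
    stack = list(reversed(list(elements)))
    while stack:
        el = stack.pop()
        if isinstance(el, RuleRef):
            if el.name not in rules:
                raise ValueError(f"dangling rule reference {el.name}")
            stack.extend(reversed(rules[el.name].expansion))
        else:
            out.append(el)
    return out


def expand(grammar: Grammar) -> SymbolSequence:
    """Depth-first expansion of the root; lossless inverse of induction."""
    symbols = _expand_elements(grammar.root, grammar.rules)
    return SymbolSequence(
        sequence_id=grammar.sequence_id or "expanded",
        category=grammar.category,
        symbols=tuple(symbols),
    )


def rule_levels(grammar: Grammar) -> dict[str, int]:
    """Hierarchy level per rule: terminals are level 1, a rule is one
    above the deepest element of its expansion.  The root is not a rule."""
    return _levels({n: r.expansion for n, r in grammar.rules.items()})


def spurious_rules(grammar: Grammar | CorpusGrammar,
                   min_occurrences: int = 3) -> dict[str, Rule]:
    """Rules with usage below ``min_occurrences`` (default: used < 3)."""
    return {n: r for n, r in grammar.rules.items() if r.usage_count < min_occurrences}


def fit_corpus(sequences: Iterable[SymbolSequence], k: int = 2) -> CorpusGrammar:
    """Induce one shared rule set over a whole corpus in a single run.

    Each sequence is kept as its own top-level string, so digram counts
    pool across sequences but no digram (hence no rule) ever spans a
    sequence boundary.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("empty corpus")
    strings, expansions, usage = _induce([list(s.symbols) for s in seqs], k)
    rules = _build_rules(expansions, usage)
    parses = tuple(
        (s.sequence_id, s.category, tuple(parse))
        for s, parse in zip(seqs, strings)
    )
    return CorpusGrammar(k=k, rules=rules, parses=parses)


def _reachable_rules(elements: Sequence, rules: Mapping[str, Rule]) -> set[str]:
    seen: set[str] = set()
    stack = [el for el in elements if isinstance(el, RuleRef)]
    while stack:
        name = stack.pop().name
        if name in seen:
            continue
        seen.add(name)
        stack.extend(el for el in rules[name].expansion if isinstance(el, RuleRef))
    return seen


def exclusive_rules(corpus: CorpusGrammar, indirect: bool = True):
    """Category-exclusive rules of a corpus grammar, counted per level.

    A rule belongs to a category when some parse of that category
    references it — directly, or (with ``indirect=True``) through a
    containing rule.  Rules referenced by exactly one category are
    *exclusive*; returns ``(exclusive: dict category -> set of rule
    names, counts: dict category -> dict level -> count)``.
    """
    used_by: dict[str, set[str]] = {n: set() for n in corpus.rules}
    for _, cat, parse in corpus.parses:
        names = (_reachable_rules(parse, corpus.rules) if indirect
                 else {el.name for el in parse if isinstance(el, RuleRef)})
        for n in names:
            used_by[n].add(cat)

    exclusive: dict[str, set[str]] = {}
    for n, cats in used_by.items():
        if len(cats) == 1:
            exclusive.setdefault(next(iter(cats)), set()).add(n)

    counts: dict[str, dict[int, int]] = {}
    for cat, names in exclusive.items():
        per_level: dict[int, int] = {}
        for n in names:
            lv = corpus.rules[n].level
            per_level[lv] = per_level.get(lv, 0) + 1
        counts[cat] = dict(sorted(per_level.items()))
    return exclusive, counts


# ---------------------------------------------------------------------------
# entropy and compression statistics
# ---------------------------------------------------------------------------

def shannon_entropy(elements: Sequence[Hashable]) -> float:
    """Empirical Shannon entropy in bits per element: H = -sum f log2 f."""
    elements = list(elements)
    if not elements:
        raise ValueError("empty element list")
    _, counts = np.unique(np.asarray([str(e) for e in elements]), return_counts=True)
    f = counts / counts.sum()
    return float(-(f * np.log2(f)).sum())


def normalized_entropy(elements: Sequence[Hashable]) -> float:
    """H divided by log2 of the number of distinct types present.

    The maximum is attained by equiprobable types; a single-type sequence
    is defined to have normalized entropy 0.
    """
    elements = list(elements)
    n_types = len({str(e) for e in elements})
    if n_types <= 1:
        return 0.0
    return shannon_entropy(elements) / float(np.log2(n_types))


@dataclass(frozen=True)
class CompressionResult:
    sequence_id: str
    category: str
    pre_length: int
    post_length: int
    ratio: float
    entropy_pre: float
    entropy_post: float
    entropy_pre_norm: float
    entropy_post_norm: float


@dataclass(frozen=True)
class CorpusCompression:
    per_sequence: tuple[CompressionResult, ...]
    slope: float
    intercept: float
    r_squared: float
    rate: float  # 1 / slope


def compress_stats(seq: SymbolSequence, grammar: Grammar) -> CompressionResult:
    """Pre/post lengths and entropies of one sequence under its parse.

    ``pre`` statistics are computed on the terminal string, ``post`` on
    the parse (root) string whose element types are terminals and rule
    ids.  The parse must expand exactly to ``seq``.
    """
    expanded = _expand_elements(grammar.root, grammar.rules)
    if tuple(expanded) != tuple(seq.symbols):
        raise ValueError(
            f"grammar root does not expand to sequence {seq.sequence_id!r}"
        )
    pre = list(seq.symbols)
    post = [str(el) for el in grammar.root]
    return CompressionResult(
        sequence_id=seq.sequence_id,
        category=seq.category,
        pre_length=len(pre),
        post_length=len(post),
        ratio=len(post) / len(pre),
        entropy_pre=shannon_entropy(pre),
        entropy_post=shannon_entropy(post),
        entropy_pre_norm=normalized_entropy(pre),
        entropy_post_norm=normalized_entropy(post),
    )


def compress_corpus(sequences: Iterable[SymbolSequence], k: int = 2) -> CorpusCompression:
    """Per-sequence k-Sequitur compression plus the pre/post regression."""
    seqs = list(sequences)
    results = [compress_stats(s, k_sequitur(s, k)) for s in seqs]
    return compression_regression(results)


def compression_regression(results: Sequence[CompressionResult]) -> CorpusCompression:
    """OLS of post-compression on pre-compression length across a corpus.

    The inverse slope is the corpus compression *rate*: how many input
    elements one compressed element stands for at the margin.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 sequences for the regression")
    pre = np.asarray([r.pre_length for r in results], dtype=float)
    post = np.asarray([r.post_length for r in results], dtype=float)
    if np.ptp(pre) == 0:
        raise ValueError("pre-compression lengths have zero variance")
    fit = stats.linregress(pre, post)
    slope = float(fit.slope)
    if slope <= 0:
        raise ValueError(f"non-positive regression slope {slope}")
    return CorpusCompression(
        per_sequence=tuple(results),
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        rate=1.0 / slope,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def format_grammar(grammar: Grammar) -> str:
    """Human-readable display: root line plus one line per rule.

    Rule expansions are shown fully expanded to terminals, with the usage
    count appended, e.g. ``r2 -> the little cat (used 4 times)``.
    """
    lines = ["Root -> " + " ".join(str(el) for el in grammar.root)]
    for name in sorted(grammar.rules, key=lambda n: int(n.lstrip("r"))):
        rule = grammar.rules[name]
        terminals = " ".join(_expand_elements(rule.expansion, grammar.rules))
        lines.append(f"{name} -> {terminals} (used {rule.usage_count} times)")
    return "\n".join(lines)


def _elements_to_json(elements: Sequence) -> list:
    return [{"ref": el.name} if isinstance(el, RuleRef) else el for el in elements]


def _elements_from_json(data: Sequence) -> tuple:
    return tuple(RuleRef(el["ref"]) if isinstance(el, dict) else el for el in data)


def grammar_to_json(grammar: Grammar, path: str | Path | None = None) -> dict:
    d = {
        "k": grammar.k,
        "sequence_id": grammar.sequence_id,
        "category": grammar.category,
        "root": _elements_to_json(grammar.root),
        "rules": {
            n: {
                "expansion": _elements_to_json(r.expansion),
                "usage_count": r.usage_count,
                "level": r.level,
            }
            for n, r in grammar.rules.items()
        },
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)
    return d


def grammar_from_json(source: str | Path | dict) -> Grammar:
    if isinstance(source, dict):
        d = source
    else:
        with open(source) as fh:
            d = json.load(fh)
    rules = {
        n: Rule(
            expansion=_elements_from_json(r["expansion"]),
            usage_count=int(r["usage_count"]),
            level=int(r["level"]),
        )
        for n, r in d["rules"].items()
    }
    return Grammar(k=int(d["k"]), root=_elements_from_json(d["root"]), rules=rules,
                   sequence_id=d.get("sequence_id", ""), category=d.get("category", ""))


# ---------------------------------------------------------------------------
# scikit-learn style estimator
# ---------------------------------------------------------------------------

class KSequitur(BaseEstimator, TransformerMixin):
    """Corpus grammar induction as a transformer.

    ``fit`` induces one shared rule set over the training corpus;
    ``transform`` parses sequences greedily against those rules
    (longest-expansion-first) and returns per-sequence compression ratios.

    Attributes
    ----------
    corpus_ : fitted :class:`CorpusGrammar`.
    n_rules_ : number of induced rules.
    """

    def __init__(self, k: int = 2):
        self.k = k

    def fit(self, X, y=None):
        from .ethogram_io import SymbolSequence as _SS

        seqs = [
            x if isinstance(x, _SS)
            else _SS(sequence_id=f"seq{i + 1}", category="", symbols=tuple(x))
            for i, x in enumerate(X)
        ]
        self.corpus_ = fit_corpus(seqs, self.k)
        self.n_rules_ = len(self.corpus_.rules)
        return self

    def transform(self, X) -> np.ndarray:
        from .complexity import cfg_covariate
        from .ethogram_io import SymbolSequence as _SS

        out = []
        for i, x in enumerate(X):
            s = (x if isinstance(x, _SS)
                 else _SS(sequence_id=f"seq{i + 1}", category="", symbols=tuple(x)))
            out.append(cfg_covariate(s, self.corpus_))
        return np.asarray(out)
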