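"""Continuous per-sequence structural-complexity covariates.

Two scalar covariates summarize how "complex-like" a short stimulus
sequence is relative to models trained on a reference corpus:

* ``delta_aic`` — AIC under a pre-fitted complex HMM minus AIC under a
  pre-fitted simple HMM, evaluated on the stimulus.  AIC (not BIC) is
  used because the stimuli are short and of variable length and AIC's
  penalty does not depend on sample size.  More negative values mean the
  complex model explains the stimulus better per parameter, i.e. higher
  structural complexity (predicting a negative BOLD correlation in
  neuroimaging use).
* ``cfg_ratio`` — post/pre compression length of the stimulus parsed
  greedily against a corpus-level k-Sequitur rule set; lower values again
  mean more exploitable structure.

Both are deterministic given the fitted models/grammar and exportable as
a covariate table for GLM packages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cfg_grammar import CorpusGrammar, RuleRef, _expand_elements
from .ethogram_io import SymbolSequence
from .hmm_grammar import HmmModel, sequence_loglik

__all__ = [
    "ComplexityCovariates",
    "hmm_covariate",
    "cfg_covariate",
    "parse_with_corpus",
    "compute_covariates",
    "export_covariates",
    "read_covariates",
    "SHORT_SEQUENCE_FLAG",
]

#: Sequences shorter than this many symbols are flagged in the export:
#: with p free parameters often exceeding the symbol count, per-stimulus
#: AIC values on such sequences are dominated by the penalty term.
SHORT_SEQUENCE_FLAG = 10


@dataclass(frozen=True)
class ComplexityCovariates:
    sequence_id: str
    category: str
    delta_aic: float
    cfg_ratio: float
    short_sequence: bool = False


def _aic(model: HmmModel, seq: SymbolSequence) -> float:
    from .hmm_grammar import n_free_params

    p = n_free_params(model.n_states, model.n_symbols)
    return -2.0 * sequence_loglik(model, seq, allow_unseen=True) + 2.0 * p


def hmm_covariate(seq: SymbolSequence, complex_model: HmmModel,
                  simple_model: HmmModel) -> float:
    """AIC(complex) - AIC(simple) on one sequence; lower = more complex.

    Each model's full free-parameter count enters its AIC even when it
    exceeds the sequence length.  Antisymmetric under swapping the two
    models.  A symbol that one model's training corpus never contained is
    carried by the emission floor; a symbol with zero mass under *both*
    models is an error.
    """
    both_dead = (complex_model.emission.max(axis=0) == 0.0) & \
                (simple_model.emission.max(axis=0) == 0.0)
    if both_dead.any():
        for pos, sym in enumerate(seq.symbols):
            if both_dead[complex_model.alphabet.index(sym)]:
                raise ValueError(
                    f"sequence {seq.sequence_id!r}: symbol {sym!r} at "
                    f"position {pos} impossible under both models"
                )
    return _aic(complex_model, seq) - _aic(simple_model, seq)


def parse_with_corpus(seq: SymbolSequence, corpus: CorpusGrammar) -> tuple:
    """Greedy longest-expansion-first parse of ``seq`` with corpus rules.

    At each position the longest rule expansion matching the upcoming
    terminals is substituted; spans matching no rule remain terminals, so
    any sequence parses.  The parse expands back to ``seq`` exactly.
    """
    by_len = sorted(
        ((tuple(_expand_elements(r.expansion, corpus.rules)), name)
         for name, r in corpus.rules.items()),
        key=lambda t: (-len(t[0]), t[1]),
    )
    symbols = tuple(seq.symbols)
    out: list = []
    i = 0
    n = len(symbols)
    while i < n:
        for exp, name in by_len:
            if symbols[i:i + len(exp)] == exp:
                out.append(RuleRef(name))
                i += len(exp)
                break
        else:
            out.append(symbols[i])
            i += 1
    return tuple(out)


def cfg_covariate(seq: SymbolSequence, corpus: CorpusGrammar) -> float:
    """Compression ratio (parse length / terminal length) in (0, 1]."""
    parse = parse_with_corpus(seq, corpus)
    return len(parse) / len(seq)


def compute_covariates(
    sequences: Iterable[SymbolSequence],
    complex_model: HmmModel,
    simple_model: HmmModel,
    corpus: CorpusGrammar,
) -> list[ComplexityCovariates]:
    out = []
    for s in sequences:
        out.append(
            ComplexityCovariates(
                sequence_id=s.sequence_id,
                category=s.category,
                delta_aic=hmm_covariate(s, complex_model, simple_model),
                cfg_ratio=cfg_covariate(s, corpus),
                short_sequence=len(s) < SHORT_SEQUENCE_FLAG,
            )
        )
    return out


def export_covariates(covariates: Sequence[ComplexityCovariates],
                      path: str | Path) -> pd.DataFrame:
    """Write the covariate table as CSV (full precision, stable columns)."""
    covs = list(covariates)
    if not covs:
        raise ValueError("no covariates to export")
    ids = [c.sequence_id for c in covs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence_id(s) {dup}")
    df = pd.DataFrame(
        {
            "sequence_id": ids,
            "category": [c.category for c in covs],
            "delta_aic": [c.delta_aic for c in covs],
            "cfg_ratio": [c.cfg_ratio for c in covs],
            "short_sequence": [c.short_sequence for c in covs],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_covariates(path: str | Path) -> list[ComplexityCovariates]:
    df = pd.read_csv(path, dtype={"sequence_id": str, "category": str})
    return [
        ComplexityCovariates(
            sequence_id=r.sequence_id,
            category="" if pd.isna(r.category) else r.category,
            delta_aic=float(r.delta_aic),
            cfg_ratio=float(r.cfg_ratio),
            short_sequence=bool(r.short_sequence),
        )
        for r in df.itertuples()
    ]
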