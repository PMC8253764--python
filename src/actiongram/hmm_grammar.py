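"""Multinomial-HMM grammar analysis of symbol sequences.

The structural complexity of a corpus of behavioral sequences is measured
by the optimal number of hidden states of a categorical-emission HMM:
models of increasing order are fitted by multi-restart Baum-Welch and
compared by BIC.  Decoded Viterbi state paths can themselves be treated as
a symbol stream and re-modelled with a second, 2-state HMM, exposing
superordinate "states-of-states" (SoS) structure — a corpus whose state
paths oscillate between two SoS regimes carries one more level of
hierarchical organisation than one that stays in a single regime.

Estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``get_params``, fitted attributes with a trailing underscore); the
module-level functions are thin wrappers kept for scripting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _hmm_kernels as _k
from .ethogram_io import DEFAULT_ALPHABET, EventAlphabet, SymbolSequence

__all__ = [
    "HmmModel",
    "FitResult",
    "ModelScan",
    "StatePath",
    "SoSResult",
    "ClassificationTie",
    "n_free_params",
    "fit_hmm",
    "information_criteria",
    "scan_states",
    "sequence_loglik",
    "classify",
    "viterbi",
    "fit_sos",
    "summarize_model",
    "state_occupancy",
    "running_sos_average",
    "match_states",
    "save_model",
    "load_model",
    "HiddenMarkovGrammar",
    "HmmOrderScan",
    "HmmSequenceClassifier",
]

#: Emission floor applied before decoding/scoring so that symbols with
#: nonzero corpus support never produce -inf from finite-sample zeros.
EMISSION_FLOOR = 1e-10

_ROW_TOL = 1e-9


class ClassificationTie(ValueError):
    """Raised when two labeled models give exactly equal log-likelihood."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HmmModel:
    """Categorical-emission HMM: initial, transition and emission rows."""

    alphabet: EventAlphabet
    initial: np.ndarray      # (S,)
    transition: np.ndarray   # (S, S) row-stochastic
    emission: np.ndarray     # (S, M) row-stochastic, columns in alphabet order

    def __post_init__(self) -> None:
        pi = np.asarray(self.initial, dtype=float)
        A = np.asarray(self.transition, dtype=float)
        B = np.asarray(self.emission, dtype=float)
        object.__setattr__(self, "initial", pi)
        object.__setattr__(self, "transition", A)
        object.__setattr__(self, "emission", B)
        S = pi.shape[0]
        if A.shape != (S, S) or B.shape != (S, len(self.alphabet)):
            raise ValueError("inconsistent HMM parameter shapes")
        for name, arr in (("initial", pi[None, :]), ("transition", A), ("emission", B)):
            if (arr < 0).any():
                raise ValueError(f"{name} has negative entries")
            if np.abs(arr.sum(axis=1) - 1.0).max() > _ROW_TOL:
                raise ValueError(f"{name} rows must sum to 1 (tol {_ROW_TOL})")

    @property
    def n_states(self) -> int:
        return self.initial.shape[0]

    @property
    def n_symbols(self) -> int:
        return len(self.alphabet)


@dataclass(frozen=True)
class FitResult:
    """Best-of-restarts Baum-Welch fit."""

    model: HmmModel
    loglik: float
    n_restarts: int
    n_free_params: int
    converged: bool
    seed: int


@dataclass(frozen=True)
class ScanRow:
    n_states: int
    fit: FitResult
    bic: float
    aic: float


@dataclass(frozen=True)
class ModelScan:
    """Per-order fits over a contiguous state-count range."""

    rows: tuple[ScanRow, ...]
    optimal_states: int

    def __getitem__(self, n_states: int) -> ScanRow:
        for r in self.rows:
            if r.n_states == n_states:
                return r
        raise KeyError(n_states)

    @property
    def best_fit(self) -> FitResult:
        return self[self.optimal_states].fit

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_states": [r.n_states for r in self.rows],
                "loglik": [r.fit.loglik for r in self.rows],
                "n_free_params": [r.fit.n_free_params for r in self.rows],
                "bic": [r.bic for r in self.rows],
                "aic": [r.aic for r in self.rows],
            }
        )


@dataclass(frozen=True)
class StatePath:
    """Viterbi-decoded state sequence; states are 1-based indices."""

    sequence_id: str
    states: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class SoSResult:
    """Second-level (states-of-states) decomposition of decoded paths."""

    sos_model: HmmModel
    sos_paths: tuple[StatePath, ...]
    occupancy: dict[str, np.ndarray]  # category -> fraction per SoS state
    degenerate: bool
    mean_switches: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_sequences(X: Iterable) -> list[SymbolSequence]:
    out: list[SymbolSequence] = []
    for i, x in enumerate(X):
        if isinstance(x, SymbolSequence):
            out.append(x)
        else:
            out.append(SymbolSequence(sequence_id=f"seq{i + 1}", category="",
                                      symbols=tuple(x)))
    if not out:
        raise ValueError("empty corpus")
    return out


def _infer_alphabet(sequences: Sequence[SymbolSequence],
                    alphabet: EventAlphabet | None) -> EventAlphabet:
    if alphabet is not None:
        for s in sequences:
            s.validate(alphabet)
        return alphabet
    seen = set()
    for s in sequences:
        seen.update(s.symbols)
    if set(DEFAULT_ALPHABET.codes) >= seen:
        return DEFAULT_ALPHABET
    return EventAlphabet(entries=tuple((c, c, "") for c in sorted(seen)))


def _encode_corpus(sequences: Sequence[SymbolSequence], alphabet: EventAlphabet):
    obs = np.concatenate(
        [np.asarray(alphabet.encode(s.symbols), dtype=np.int64) for s in sequences]
    )
    lengths = np.asarray([len(s) for s in sequences], dtype=np.int64)
    ends = np.cumsum(lengths)
    starts = ends - lengths
    return obs, starts, ends


def n_free_params(n_states: int, n_symbols: int) -> int:
    """Free parameters of a categorical HMM, initial distribution included."""
    S, M = n_states, n_symbols
    return S * (S - 1) + S * (M - 1) + (S - 1)


def _dirichlet_rows(rng: np.random.Generator, n_rows: int, n_cols: int) -> np.ndarray:
    # symmetric Dirichlet(1) == row-normalized exponentials
    g = rng.exponential(size=(n_rows, n_cols))
    return g / g.sum(axis=1, keepdims=True)


def _floored_emission(B: np.ndarray) -> np.ndarray:
    Bf = np.maximum(B, EMISSION_FLOOR)
    return Bf


def _check_symbol_support(model: HmmModel, seq: SymbolSequence,
                          allow_unseen: bool = False) -> np.ndarray:
    try:
        obs = np.asarray(model.alphabet.encode(seq.symbols), dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"sequence {seq.sequence_id!r}: {exc.args[0]}") from None
    if allow_unseen:
        return obs
    dead = model.emission.max(axis=0) == 0.0
    if dead[obs].any():
        pos = int(np.argmax(dead[obs]))
        raise ValueError(
            f"sequence {seq.sequence_id!r}: symbol {seq.symbols[pos]!r} at "
            f"position {pos} has zero emission mass in every state"
        )
    return obs


# ---------------------------------------------------------------------------
# fitting and model selection
# ---------------------------------------------------------------------------

def _run_em(obs, starts, ends, pi, A, B, tol: float, max_iter: int):
    """EM to convergence from one start; returns (loglik, pi, A, B, converged)."""
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        ll, pi2, A2, B2 = _k.em_step(obs, starts, ends, pi, A, B)
        if not np.isfinite(ll):
            return -np.inf, pi, A, B, False
        if ll < prev - 1e-6:
            raise RuntimeError(
                f"Baum-Welch log-likelihood decreased ({prev:.9g} -> {ll:.9g})"
            )
        pi, A, B = pi2, A2, B2
        if ll - prev < tol:
            converged = True
            prev = ll
            break
        prev = ll
    return prev, pi, A, B, converged


def fit_hmm(
    sequences: Iterable,
    n_states: int,
    n_restarts: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    alphabet: EventAlphabet | None = None,
) -> FitResult:
    """Fit an ``n_states``-state categorical HMM by best-of-restarts EM.

    Each restart draws initial, transition and emission rows from a
    symmetric Dirichlet(1); sufficient statistics are summed across all
    sequences; the restart with the highest total log-likelihood wins.
    Reproducible given ``seed`` (one master seed spawns per-restart seeds).
    """
    seqs = _as_sequences(sequences)
    alphabet = _infer_alphabet(seqs, alphabet)
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    obs, starts, ends = _encode_corpus(seqs, alphabet)
    if n_states > obs.shape[0]:
        raise ValueError(
            f"n_states={n_states} exceeds total symbol count {obs.shape[0]}"
        )
    M = len(alphabet)

    master = np.random.default_rng(seed)
    restart_seeds = master.integers(0, 2**31 - 1, size=n_restarts)

    best = (-np.inf, None, False)
    for rs in restart_seeds:
        rng = np.random.default_rng(int(rs))
        pi = _dirichlet_rows(rng, 1, n_states)[0]
        A = _dirichlet_rows(rng, n_states, n_states)
        B = _dirichlet_rows(rng, n_states, M)
        ll, pi, A, B, conv = _run_em(obs, starts, ends, pi, A, B, tol, max_iter)
        if ll > best[0]:
            best = (ll, (pi, A, B), conv)

    ll, params, conv = best
    if params is None:
        raise RuntimeError("all restarts failed (zero-probability corpus)")
    pi, A, B = params
    # EM leaves rows stochastic up to rounding; renormalize exactly
    pi = pi / pi.sum()
    A = A / A.sum(axis=1, keepdims=True)
    B = B / B.sum(axis=1, keepdims=True)
    model = HmmModel(alphabet=alphabet, initial=pi, transition=A, emission=B)
    return FitResult(
        model=model,
        loglik=float(ll),
        n_restarts=n_restarts,
        n_free_params=n_free_params(n_states, M),
        converged=bool(conv),
        seed=seed,
    )


def information_criteria(fit: FitResult, n_obs: int) -> tuple[float, float]:
    """(BIC, AIC) = (-2 LL + p ln n, -2 LL + 2 p)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    p = fit.n_free_params
    bic = -2.0 * fit.loglik + p * math.log(n_obs)
    aic = -2.0 * fit.loglik + 2.0 * p
    return bic, aic


def scan_states(
    sequences: Iterable,
    s_range: Iterable[int] = range(1, 13),
    n_restarts: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    alphabet: EventAlphabet | None = None,
) -> ModelScan:
    """Fit every state count in ``s_range``; pick argmin-BIC (ties: smaller S).

    n for the BIC penalty is the total number of emitted symbols in the
    corpus — the observations are the emissions.
    """
    seqs = _as_sequences(sequences)
    s_list = sorted(set(int(s) for s in s_range))
    if not s_list:
        raise ValueError("empty state-count range")
    if s_list != list(range(s_list[0], s_list[-1] + 1)):
        raise ValueError("state-count range must be contiguous")
    n_obs = sum(len(s) for s in seqs)
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=len(s_list))
    rows = []
    for S, sub in zip(s_list, sub_seeds):
        fit = fit_hmm(seqs, S, n_restarts=n_restarts, seed=int(sub), tol=tol,
                      max_iter=max_iter, alphabet=alphabet)
        bic, aic = information_criteria(fit, n_obs)
        rows.append(ScanRow(n_states=S, fit=fit, bic=bic, aic=aic))
    best = min(rows, key=lambda r: (r.bic, r.n_states))
    return ModelScan(rows=tuple(rows), optimal_states=best.n_states)


# ---------------------------------------------------------------------------
# scoring and decoding
# ---------------------------------------------------------------------------

def sequence_loglik(model: HmmModel, seq: SymbolSequence,
                    allow_unseen: bool = False) -> float:
    """Forward-algorithm log-likelihood of one sequence under ``model``.

    Emission probabilities are floored at 1e-10 so that symbols absent
    from a state's training support still score finitely; a symbol with
    zero mass in *every* state is an error unless ``allow_unseen`` is
    set, in which case the floor alone carries it (used when scoring a
    sequence under a model trained on a different category whose corpus
    simply never contained that action).
    """
    obs = _check_symbol_support(model, seq, allow_unseen=allow_unseen)
    B = _floored_emission(model.emission)
    ll, fail = _k.forward_loglik(obs, model.initial, model.transition, B)
    if fail >= 0:
        raise ValueError(
            f"sequence {seq.sequence_id!r} impossible under model at position {fail}"
        )
    return float(ll)


def classify(models: Mapping[str, HmmModel], seq: SymbolSequence) -> str:
    """Label of the model with the highest per-sequence log-likelihood.

    An exact tie raises :class:`ClassificationTie` rather than silently
    picking one label.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 labeled models")
    # a symbol only has to be possible under at least one candidate model
    alive = np.zeros(len(next(iter(models.values())).alphabet.codes), dtype=bool)
    for m in models.values():
        alive |= m.emission.max(axis=0) > 0.0
    for pos, sym in enumerate(seq.symbols):
        if not alive[next(iter(models.values())).alphabet.index(sym)]:
            raise ValueError(
                f"sequence {seq.sequence_id!r}: symbol {sym!r} at position "
                f"{pos} impossible under every candidate model"
            )
    lls = {label: sequence_loglik(m, seq, allow_unseen=True)
           for label, m in models.items()}
    best = max(lls.values())
    winners = [label for label, v in lls.items() if v == best]
    if len(winners) > 1:
        raise ClassificationTie(
            f"sequence {seq.sequence_id!r}: exact log-likelihood tie among {winners}"
        )
    return winners[0]


def viterbi(model: HmmModel, seq: SymbolSequence) -> StatePath:
    """Most likely state path (1-based states); ties go to the lower index."""
    obs = _check_symbol_support(model, seq)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.initial)
        log_A = np.log(model.transition)
        log_B = np.log(_floored_emission(model.emission))
    path, _, fail = _k.viterbi_path(obs, log_pi, log_A, log_B)
    if fail >= 0:
        raise ValueError(
            f"sequence {seq.sequence_id!r} impossible under model at position {fail}"
        )
    return StatePath(sequence_id=seq.sequence_id,
                     states=tuple(int(s) + 1 for s in path))


def state_occupancy(model: HmmModel, sequences: Iterable) -> np.ndarray:
    """Fraction of Viterbi-decoded positions spent in each state."""
    seqs = _as_sequences(sequences)
    counts = np.zeros(model.n_states)
    for s in seqs:
        path = viterbi(model, s)
        for st in path.states:
            counts[st - 1] += 1
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# states-of-states
# ---------------------------------------------------------------------------

def _state_alphabet(n_states: int) -> EventAlphabet:
    n = max(n_states, 2)
    return EventAlphabet(entries=tuple((f"s{i}", f"state {i}", "") for i in range(1, n + 1)))


def fit_sos(
    paths: Iterable[StatePath],
    seed: int = 0,
    n_restarts: int = 100,
    categories: Mapping[str, str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> SoSResult:
    """Fit a 2-state HMM to decoded state paths ("states of states").

    State indices become a new terminal alphabet; the 2-state model is fit
    with the same restart protocol, each path is Viterbi-decoded to an SoS
    path, and per-category SoS occupancy fractions are reported.  All
    paths should come from one shared model (typically the selected model
    of the more complex category, so that the simpler category's paths are
    expressed in the same state vocabulary).  Constant input paths do not
    fail, but the result is flagged degenerate.
    """
    path_list = list(paths)
    if not path_list:
        raise ValueError("no state paths")
    max_state = max(max(p.states) for p in path_list)
    alphabet = _state_alphabet(max_state)
    seqs = [
        SymbolSequence(
            sequence_id=p.sequence_id,
            category=(categories or {}).get(p.sequence_id, ""),
            symbols=tuple(f"s{s}" for s in p.states),
        )
        for p in path_list
    ]
    degenerate = all(len(set(p.states)) == 1 for p in path_list)
    fit = fit_hmm(seqs, 2, n_restarts=n_restarts, seed=seed, tol=tol,
                  max_iter=max_iter, alphabet=alphabet)
    sos_paths = tuple(viterbi(fit.model, s) for s in seqs)

    occupancy: dict[str, np.ndarray] = {}
    switches: dict[str, list[int]] = {}
    for s, sp in zip(seqs, sos_paths):
        occ = occupancy.setdefault(s.category, np.zeros(2))
        for st in sp.states:
            occ[st - 1] += 1
        n_sw = sum(a != b for a, b in zip(sp.states, sp.states[1:]))
        switches.setdefault(s.category, []).append(n_sw)
    occupancy = {c: v / v.sum() for c, v in occupancy.items()}
    mean_switches = {c: float(np.mean(v)) for c, v in switches.items()}
    return SoSResult(
        sos_model=fit.model,
        sos_paths=sos_paths,
        occupancy=occupancy,
        degenerate=degenerate,
        mean_switches=mean_switches,
    )


def running_sos_average(path: StatePath, window: int = 9) -> np.ndarray:
    """Centered moving mean of the binary SoS indicator (state 2 -> 1).

    ``window`` must be odd; windows are truncated at the edges so the
    output has the same length as the path.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    n = len(path.states)
    if window > n:
        raise ValueError(f"window {window} exceeds path length {n}")
    ind = np.asarray([1.0 if s == 2 else 0.0 for s in path.states])
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(ind)])
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


# ---------------------------------------------------------------------------
# presentation and persistence
# ---------------------------------------------------------------------------

def summarize_model(model: HmmModel, display_floor: float = 0.05) -> pd.DataFrame:
    """Readable edge/emission table with entries below ``display_floor`` hidden.

    Mirrors the usual graph rendering of an HMM where arrows and pie
    slices under the floor are not drawn.  The model itself is untouched.
    """
    if not 0 <= display_floor < 1:
        raise ValueError("display_floor must be in [0, 1)")
    rows = []
    for i in range(model.n_states):
        for j in range(model.n_states):
            p = model.transition[i, j]
            if p >= display_floor and p > 0:
                rows.append(("transition", f"state {i + 1}", f"state {j + 1}", p))
    for i in range(model.n_states):
        for m, code in enumerate(model.alphabet.codes):
            p = model.emission[i, m]
            if p >= display_floor and p > 0:
                rows.append(("emission", f"state {i + 1}", code, p))
    return pd.DataFrame(rows, columns=["kind", "from", "to", "probability"])


def match_states(emission_a: np.ndarray, emission_b: np.ndarray) -> np.ndarray:
    """Optimal state relabeling between two emission matrices.

    Returns the permutation ``perm`` minimizing the summed total-variation
    distance between ``emission_a[perm]`` and ``emission_b`` (Hungarian
    assignment).  State labels are arbitrary across runs; any cross-run
    comparison must go through this matching, never raw indices.
    """
    S = emission_a.shape[0]
    cost = np.empty((S, S))
    for i in range(S):
        for j in range(S):
            cost[i, j] = 0.5 * np.abs(emission_a[i] - emission_b[j]).sum()
    row, col = linear_sum_assignment(cost)
    perm = np.empty(S, dtype=int)
    perm[col] = row
    return perm


def _model_to_dict(model: HmmModel) -> dict:
    return {
        "alphabet": {c: l for c, l, _ in model.alphabet.entries},
        "n_states": model.n_states,
        "initial": model.initial.tolist(),
        "transition": model.transition.tolist(),
        "emission": model.emission.tolist(),
    }


def save_model(model: HmmModel, path: str | Path) -> None:
    """Write a model as YAML or JSON (by extension), full precision."""
    path = Path(path)
    d = _model_to_dict(model)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(d, fh, sort_keys=False)
        else:
            json.dump(d, fh, indent=1)


def load_model(path: str | Path) -> HmmModel:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
    alphabet = EventAlphabet(entries=tuple((c, l, "") for c, l in d["alphabet"].items()))
    return HmmModel(
        alphabet=alphabet,
        initial=np.asarray(d["initial"], dtype=float),
        transition=np.asarray(d["transition"], dtype=float),
        emission=np.asarray(d["emission"], dtype=float),
    )


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------

class HiddenMarkovGrammar(BaseEstimator):
    """Best-of-restarts categorical HMM with a fixed number of states.

    Parameters
    ----------
    n_states : hidden-state count S.
    n_restarts : Baum-Welch restarts; the highest-likelihood fit is kept.
    tol, max_iter : EM stopping rule (absolute log-likelihood improvement).
    random_state : master seed spawning per-restart seeds.
    alphabet : terminal alphabet; inferred from the data when None.

    Attributes
    ----------
    model_ : fitted :class:`HmmModel`.
    fit_result_ : full :class:`FitResult` (loglik, p, convergence, seed).
    loglik_ : total training log-likelihood of the winning restart.
    """

    def __init__(self, n_states: int = 2, n_restarts: int = 100,
                 tol: float = 1e-6, max_iter: int = 500,
                 random_state: int = 0, alphabet: EventAlphabet | None = None):
        self.n_states = n_states
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.alphabet = alphabet

    def fit(self, X, y=None):
        self.fit_result_ = fit_hmm(
            X, self.n_states, n_restarts=self.n_restarts,
            seed=self.random_state, tol=self.tol, max_iter=self.max_iter,
            alphabet=self.alphabet,
        )
        self.model_ = self.fit_result_.model
        self.loglik_ = self.fit_result_.loglik
        self.n_obs_ = sum(len(s) for s in _as_sequences(X))
        return self

    def score_sequences(self, X) -> np.ndarray:
        return np.asarray([sequence_loglik(self.model_, s) for s in _as_sequences(X)])

    def score(self, X, y=None) -> float:
        return float(self.score_sequences(X).sum())

    def decode(self, X) -> list[StatePath]:
        return [viterbi(self.model_, s) for s in _as_sequences(X)]

    def bic(self, n_obs: int | None = None) -> float:
        return information_criteria(self.fit_result_, n_obs or self.n_obs_)[0]

    def aic(self) -> float:
        return information_criteria(self.fit_result_, max(self.n_obs_, 1))[1]


class HmmOrderScan(BaseEstimator):
    """Model-order selection: fit S = min_states..max_states, argmin BIC."""

    def __init__(self, min_states: int = 1, max_states: int = 12,
                 n_restarts: int = 100, tol: float = 1e-6, max_iter: int = 500,
                 random_state: int = 0, alphabet: EventAlphabet | None = None):
        self.min_states = min_states
        self.max_states = max_states
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.alphabet = alphabet

    def fit(self, X, y=None):
        self.scan_ = scan_states(
            X, range(self.min_states, self.max_states + 1),
            n_restarts=self.n_restarts, seed=self.random_state,
            tol=self.tol, max_iter=self.max_iter, alphabet=self.alphabet,
        )
        self.optimal_states_ = self.scan_.optimal_states
        self.best_model_ = self.scan_.best_fit.model
        return self


class HmmSequenceClassifier(BaseEstimator, ClassifierMixin):
    """Cross-likelihood sequence classifier: one HMM per category.

    Per category, either a fixed state count (``n_states`` int or mapping
    label -> S) is fitted, or the order is selected by BIC over
    ``min_states..max_states``.  ``predict`` assigns the label whose model
    gives the highest forward log-likelihood; exact ties raise
    :class:`ClassificationTie`.
    """

    def __init__(self, n_states=None, min_states: int = 1, max_states: int = 8,
                 n_restarts: int = 100, random_state: int = 0,
                 alphabet: EventAlphabet | None = None):
        self.n_states = n_states
        self.min_states = min_states
        self.max_states = max_states
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.alphabet = alphabet

    def fit(self, X, y):
        seqs = _as_sequences(X)
        y = list(y)
        if len(y) != len(seqs):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.asarray(sorted(set(y)))
        master = np.random.default_rng(self.random_state)
        self.models_: dict[str, HmmModel] = {}
        self.orders_: dict[str, int] = {}
        for label in self.classes_:
            sub = [s for s, lab in zip(seqs, y) if lab == label]
            sub_seed = int(master.integers(0, 2**31 - 1))
            if self.n_states is None:
                scan = scan_states(sub, range(self.min_states, self.max_states + 1),
                                   n_restarts=self.n_restarts, seed=sub_seed,
                                   alphabet=self.alphabet)
                S = scan.optimal_states
                self.models_[label] = scan.best_fit.model
            else:
                S = (self.n_states[label] if isinstance(self.n_states, Mapping)
                     else int(self.n_states))
                self.models_[label] = fit_hmm(
                    sub, S, n_restarts=self.n_restarts, seed=sub_seed,
                    alphabet=self.alphabet).model
            self.orders_[label] = S
        return self

    def predict_loglik(self, X) -> pd.DataFrame:
        seqs = _as_sequences(X)
        return pd.DataFrame(
            {lab: [sequence_loglik(m, s) for s in seqs]
             for lab, m in self.models_.items()},
            index=[s.sequence_id for s in seqs],
        )

    def predict(self, X) -> np.ndarray:
        return np.asarray([classify(self.models_, s) for s in _as_sequences(X)])
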