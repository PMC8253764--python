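import numpy as np
import pytest

from actiongram.ethogram_io import DEFAULT_ALPHABET, SymbolSequence
from actiongram.hmm_grammar import HmmModel


def make_sequence(symbols, sequence_id="s", category=""):
    return SymbolSequence(sequence_id=sequence_id, category=category,
                          symbols=tuple(symbols))


@pytest.fixture(scope="session")
def alphabet():
    return DEFAULT_ALPHABET


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_model(n_states, alphabet=DEFAULT_ALPHABET, seed=0):
    """Dense random HMM (strictly positive rows) for oracle comparisons."""
    rng = np.random.default_rng(seed)
    M = len(alphabet)

    def rows(n, m):
        g = rng.random((n, m)) + 0.05
        return g / g.sum(axis=1, keepdims=True)

    return HmmModel(
        alphabet=alphabet,
        initial=rows(1, n_states)[0],
        transition=rows(n_states, n_states),
        emission=rows(n_states, M),
    )


def brute_force_loglik(model, symbols):
    """Exhaustive sum over all state paths (oracle; S**T terms)."""
    import itertools

    obs = [model.alphabet.index(s) for s in symbols]
    total = 0.0
    S = model.n_states
    for path in itertools.product(range(S), repeat=len(obs)):
        p = model.initial[path[0]] * model.emission[path[0], obs[0]]
        for t in range(1, len(obs)):
            p *= model.transition[path[t - 1], path[t]] * model.emission[path[t], obs[t]]
        total += p
    return np.log(total)


def brute_force_viterbi(model, symbols):
    """Exhaustive max over all state paths; ties to lexicographically
    smallest path, matching the decoder's lower-index backtrack rule."""
    import itertools

    obs = [model.alphabet.index(s) for s in symbols]
    S = model.n_states
    best_p, best_path = -np.inf, None
    for path in itertools.product(range(S), repeat=len(obs)):
        p = np.log(model.initial[path[0]]) + np.log(model.emission[path[0], obs[0]])
        for t in range(1, len(obs)):
            p += np.log(model.transition[path[t - 1], path[t]])
            p += np.log(model.emission[path[t], obs[t]])
        if p > best_p:
            best_p, best_path = p, path
    return best_p, tuple(s + 1 for s in best_path)
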