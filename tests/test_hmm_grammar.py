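"""HMM numerics against exhaustive oracles, fitting, selection, SoS."""

import math

import numpy as np
import pytest

from actiongram.ethogram_io import DEFAULT_ALPHABET, EventAlphabet
from actiongram.hmm_grammar import (
    ClassificationTie,
    HiddenMarkovGrammar,
    HmmModel,
    HmmOrderScan,
    HmmSequenceClassifier,
    StatePath,
    classify,
    fit_hmm,
    fit_sos,
    information_criteria,
    load_model,
    match_states,
    n_free_params,
    running_sos_average,
    save_model,
    scan_states,
    sequence_loglik,
    state_occupancy,
    summarize_model,
    viterbi,
)
from actiongram.synthetic_data import sample_from_hmm, well_separated_hmm

from conftest import (
    brute_force_loglik,
    brute_force_viterbi,
    make_sequence,
    random_model,
)

AB2 = EventAlphabet(entries=(("a", "a", ""), ("b", "b", "")))


def two_state_ab(p_stay=0.9):
    """Near-deterministic 2-state model: state 1 emits a, state 2 emits b."""
    return HmmModel(
        alphabet=AB2,
        initial=[0.5, 0.5],
        transition=[[p_stay, 1 - p_stay], [1 - p_stay, p_stay]],
        emission=[[0.99, 0.01], [0.01, 0.99]],
    )


class TestOracleEquivalence:
    """Forward and Viterbi against exhaustive path enumeration."""

    @pytest.mark.parametrize("n_states,length,seed", [
        (2, 5, 0), (2, 8, 1), (3, 6, 2), (3, 8, 3), (4, 7, 4), (4, 8, 5),
    ])
    def test_forward_matches_path_sum(self, n_states, length, seed):
        model = random_model(n_states, seed=seed)
        rng = np.random.default_rng(seed + 100)
        symbols = [DEFAULT_ALPHABET.codes[i]
                   for i in rng.integers(0, 7, size=length)]
        seq = make_sequence(symbols)
        assert sequence_loglik(model, seq) == pytest.approx(
            brute_force_loglik(model, symbols), abs=1e-8)

    @pytest.mark.parametrize("n_states,length,seed", [
        (2, 6, 10), (3, 7, 11), (4, 8, 12),
    ])
    def test_viterbi_matches_exhaustive_max(self, n_states, length, seed):
        model = random_model(n_states, seed=seed)
        rng = np.random.default_rng(seed + 100)
        symbols = [DEFAULT_ALPHABET.codes[i]
                   for i in rng.integers(0, 7, size=length)]
        best_p, best_path = brute_force_viterbi(model, symbols)
        path = viterbi(model, make_sequence(symbols))
        assert path.states == best_path
        # decoded path's own log-probability equals the exhaustive max
        obs = [model.alphabet.index(s) for s in symbols]
        lp = math.log(model.initial[path.states[0] - 1]) + \
            math.log(model.emission[path.states[0] - 1, obs[0]])
        for t in range(1, length):
            lp += math.log(model.transition[path.states[t - 1] - 1,
                                            path.states[t] - 1])
            lp += math.log(model.emission[path.states[t] - 1, obs[t]])
        assert lp == pytest.approx(best_p, abs=1e-8)

    def test_forward_agrees_with_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        model = random_model(3, seed=7)
        ref = hmmlearn.CategoricalHMM(n_components=3)
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.emissionprob_ = model.emission
        rng = np.random.default_rng(0)
        obs = rng.integers(0, 7, size=300)
        seq = make_sequence([DEFAULT_ALPHABET.codes[i] for i in obs])
        assert sequence_loglik(model, seq) == pytest.approx(
            ref.score(obs.reshape(-1, 1)), abs=1e-6)

    def test_no_underflow_on_long_sequences(self):
        model = random_model(3, seed=3)
        rng = np.random.default_rng(1)
        seq = make_sequence([DEFAULT_ALPHABET.codes[i]
                             for i in rng.integers(0, 7, size=2000)])
        ll = sequence_loglik(model, seq)
        assert np.isfinite(ll) and ll < 0


class TestDegenerateAndTies:
    def test_deterministic_one_state_model_scores_zero(self):
        m = HmmModel(alphabet=AB2, initial=[1.0], transition=[[1.0]],
                     emission=[[1.0, 0.0]])
        assert sequence_loglik(m, make_sequence("aaaa")) == pytest.approx(0.0)

    def test_impossible_symbol_reports_position(self):
        m = HmmModel(alphabet=AB2, initial=[1.0], transition=[[1.0]],
                     emission=[[1.0, 0.0]])
        with pytest.raises(ValueError, match="position 2"):
            sequence_loglik(m, make_sequence("aab"))
        with pytest.raises(ValueError, match="position 2"):
            viterbi(m, make_sequence("aab"))

    def test_identity_emission_path_mirrors_symbols(self):
        m = HmmModel(alphabet=AB2, initial=[0.5, 0.5],
                     transition=[[0.5, 0.5], [0.5, 0.5]],
                     emission=[[1.0, 0.0], [0.0, 1.0]])
        path = viterbi(m, make_sequence("abba"))
        assert path.states == (1, 2, 2, 1)

    def test_uniform_model_all_ties_constant_lowest_state(self):
        m = HmmModel(alphabet=AB2, initial=[0.5, 0.5],
                     transition=[[0.5, 0.5], [0.5, 0.5]],
                     emission=[[0.5, 0.5], [0.5, 0.5]])
        path = viterbi(m, make_sequence("abab"))
        assert path.states == (1, 1, 1, 1)


class TestFitting:
    def test_single_symbol_corpus_closed_form(self):
        fit = fit_hmm([make_sequence("aaaa")], 1, n_restarts=3, seed=0,
                      alphabet=AB2)
        assert fit.loglik == pytest.approx(0.0, abs=1e-9)
        assert fit.model.emission[0, 0] == pytest.approx(1.0)

    def test_best_of_restarts_dominates_single_restart(self):
        m = two_state_ab()
        seqs = [sample_from_hmm(m, 100, seed=i) for i in range(4)]
        multi = fit_hmm(seqs, 2, n_restarts=8, seed=5)
        for restart_seed in range(3):
            single = fit_hmm(seqs, 2, n_restarts=1, seed=restart_seed)
            assert multi.loglik >= single.loglik - 1e-9

    def test_loglik_nonpositive_and_rows_stochastic(self):
        m = two_state_ab()
        seqs = [sample_from_hmm(m, 80, seed=i) for i in range(3)]
        fit = fit_hmm(seqs, 3, n_restarts=5, seed=1)
        assert fit.loglik <= 0
        np.testing.assert_allclose(fit.model.transition.sum(axis=1), 1, atol=1e-9)
        np.testing.assert_allclose(fit.model.emission.sum(axis=1), 1, atol=1e-9)
        np.testing.assert_allclose(fit.model.initial.sum(), 1, atol=1e-9)

    def test_reproducible_given_seed(self):
        m = two_state_ab()
        seqs = [sample_from_hmm(m, 60, seed=i) for i in range(3)]
        f1 = fit_hmm(seqs, 2, n_restarts=5, seed=9)
        f2 = fit_hmm(seqs, 2, n_restarts=5, seed=9)
        np.testing.assert_array_equal(f1.model.emission, f2.model.emission)
        assert f1.loglik == f2.loglik

    def test_too_many_states_rejected(self):
        with pytest.raises(ValueError):
            fit_hmm([make_sequence("ab")], 5, n_restarts=1, alphabet=AB2)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_hmm([], 2, n_restarts=1)

    def test_parameter_recovery_planted_three_states(self):
        planted = well_separated_hmm(3, seed=11)
        seqs = [sample_from_hmm(planted, 200, seed=500 + i, sequence_id=f"s{i}")
                for i in range(20)]
        fit = fit_hmm(seqs, 3, n_restarts=25, seed=3)
        perm = match_states(fit.model.emission, planted.emission)
        tv = 0.5 * np.abs(fit.model.emission[perm] - planted.emission).sum(axis=1)
        assert tv.max() < 0.05


class TestInformationCriteria:
    def test_formulas(self):
        fit = fit_hmm([make_sequence("aaaa")], 1, n_restarts=1, alphabet=AB2)
        # loglik 0, p = 1 for S=1, M=2
        bic, aic = information_criteria(fit, 10)
        assert bic == pytest.approx(fit.n_free_params * math.log(10))
        assert aic == pytest.approx(2 * fit.n_free_params)

    def test_free_param_count(self):
        assert n_free_params(6, 7) == 6 * 5 + 6 * 6 + 5
        assert n_free_params(1, 2) == 1

    def test_aic_below_bic_beyond_e_squared(self):
        fit = fit_hmm([make_sequence("aaaa")], 1, n_restarts=1, alphabet=AB2)
        bic8, aic8 = information_criteria(fit, 8)     # 8 > e^2
        bic7, aic7 = information_criteria(fit, 7)     # 7 < e^2
        assert aic8 < bic8 and aic7 > bic7

    def test_larger_model_fits_no_worse(self):
        m = two_state_ab()
        seqs = [sample_from_hmm(m, 100, seed=i) for i in range(5)]
        lls = [fit_hmm(seqs, S, n_restarts=10, seed=4).loglik for S in (1, 2, 3)]
        assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6


class TestModelSelection:
    def test_single_repeated_symbol_selects_one_state(self):
        seqs = [make_sequence("a" * 30, sequence_id=f"s{i}") for i in range(3)]
        scan = scan_states(seqs, range(1, 4), n_restarts=3, seed=0, alphabet=AB2)
        assert scan.optimal_states == 1

    def test_recovers_planted_order(self):
        planted = well_separated_hmm(3, seed=2)
        seqs = [sample_from_hmm(planted, 200, seed=900 + i) for i in range(10)]
        scan = scan_states(seqs, range(1, 6), n_restarts=10, seed=1)
        assert scan.optimal_states == 3

    def test_scan_report_columns(self):
        seqs = [make_sequence("abab" * 5)]
        df = scan_states(seqs, range(1, 3), n_restarts=3, seed=0,
                         alphabet=AB2).to_frame()
        assert list(df.columns) == ["n_states", "loglik", "n_free_params",
                                    "bic", "aic"]


class TestClassification:
    def test_identical_models_tie(self):
        m = two_state_ab()
        with pytest.raises(ClassificationTie):
            classify({"A": m, "B": m}, make_sequence("abab"))

    def test_samples_classified_to_their_generator(self):
        gen_a = well_separated_hmm(2, self_loop=0.95, seed=1)
        gen_b = well_separated_hmm(4, self_loop=0.6, seed=8)
        models = {"A": gen_a, "B": gen_b}
        correct = 0
        n = 100
        for i in range(n):
            s = sample_from_hmm(gen_a, 200, seed=2000 + i)
            correct += classify(models, s) == "A"
        assert correct >= 95

    def test_classifier_estimator_end_to_end(self):
        gen_a = well_separated_hmm(2, self_loop=0.95, seed=1)
        gen_b = well_separated_hmm(4, self_loop=0.6, seed=8)
        X = [sample_from_hmm(gen_a, 120, seed=i, category="A") for i in range(6)]
        X += [sample_from_hmm(gen_b, 120, seed=50 + i, category="B") for i in range(6)]
        y = [s.category for s in X]
        clf = HmmSequenceClassifier(n_states={"A": 2, "B": 4}, n_restarts=10,
                                    random_state=0).fit(X, y)
        assert (clf.predict(X) == np.asarray(y)).mean() == 1.0
        assert clf.predict_loglik(X).shape == (12, 2)


class TestStatesOfStates:
    def _regime_paths(self, n=8, length=120, seed=0):
        """Paths alternating between a {1,2}-regime and a {3,4}-regime."""
        rng = np.random.default_rng(seed)
        paths = []
        for i in range(n):
            states, regime = [], 0
            while len(states) < length:
                run = int(rng.integers(8, 20))
                lo = 1 if regime == 0 else 3
                states.extend(int(rng.integers(lo, lo + 2)) for _ in range(run))
                regime = 1 - regime
            paths.append(StatePath(sequence_id=f"p{i}", states=tuple(states[:length])))
        return paths

    def test_oscillating_vs_single_regime_categories(self):
        """Fit SoS on a combined corpus, as the protocol prescribes: paths
        of one category oscillate between the {1,2} and {3,4} regimes,
        the other category never leaves {1,2} and must stay in one SoS."""
        rng = np.random.default_rng(5)
        osc = self._regime_paths(n=6)
        flat = [StatePath(sequence_id=f"f{i}",
                          states=tuple(int(rng.integers(1, 3)) for _ in range(100)))
                for i in range(6)]
        cats = {p.sequence_id: "osc" for p in osc}
        cats.update({p.sequence_id: "flat" for p in flat})
        res = fit_sos(osc + flat, seed=0, n_restarts=10, categories=cats)
        assert not res.degenerate
        occ_osc = res.occupancy["osc"]
        assert occ_osc.sum() == pytest.approx(1.0)
        assert occ_osc.min() >= 0.10
        assert res.mean_switches["osc"] >= 3
        assert res.occupancy["flat"].max() >= 0.98

    def test_constant_paths_flagged_degenerate(self):
        paths = [StatePath(sequence_id=f"p{i}", states=(1,) * 50) for i in range(3)]
        res = fit_sos(paths, seed=0, n_restarts=3)
        assert res.degenerate

    def test_occupancy_sums_to_one_per_category(self):
        paths = self._regime_paths(n=4)
        cats = {p.sequence_id: ("A" if i < 2 else "B")
                for i, p in enumerate(paths)}
        res = fit_sos(paths, seed=1, n_restarts=5, categories=cats)
        for occ in res.occupancy.values():
            assert occ.sum() == pytest.approx(1.0)


class TestRunningAverage:
    def test_constant_path_constant_series(self):
        p = StatePath(sequence_id="p", states=(2,) * 20)
        np.testing.assert_allclose(running_sos_average(p, 5), 1.0)

    def test_window_one_is_indicator(self):
        p = StatePath(sequence_id="p", states=(1, 2, 2, 1))
        np.testing.assert_allclose(running_sos_average(p, 1), [0, 1, 1, 0])

    def test_alternating_window_three(self):
        p = StatePath(sequence_id="p", states=(1, 2) * 5)
        out = running_sos_average(p, 3)
        interior = out[1:-1]
        assert set(np.round(interior, 6)) <= {round(1 / 3, 6), round(2 / 3, 6)}

    def test_window_validation(self):
        p = StatePath(sequence_id="p", states=(1, 2, 1))
        with pytest.raises(ValueError):
            running_sos_average(p, 4)
        with pytest.raises(ValueError):
            running_sos_average(p, 5)


class TestPresentationAndPersistence:
    def test_summary_floor_zero_keeps_everything(self):
        m = two_state_ab()
        df = summarize_model(m, 0.0)
        assert len(df[df.kind == "transition"]) == 4
        assert len(df[df.kind == "emission"]) == 4

    def test_summary_floor_suppresses_weak_edges(self):
        m = two_state_ab(p_stay=0.97)
        df = summarize_model(m, 0.05)
        assert len(df[df.kind == "transition"]) == 2  # only the self-loops
        # purity: model untouched
        assert m.transition[0, 1] == pytest.approx(0.03)

    def test_state_occupancy_sums_to_one(self):
        m = two_state_ab()
        seqs = [sample_from_hmm(m, 100, seed=i) for i in range(3)]
        occ = state_occupancy(m, seqs)
        assert occ.sum() == pytest.approx(1.0)
        assert occ.shape == (2,)

    def test_one_state_model_occupancy_is_one(self):
        m = HmmModel(alphabet=AB2, initial=[1.0], transition=[[1.0]],
                     emission=[[0.6, 0.4]])
        occ = state_occupancy(m, [make_sequence("abab")])
        assert occ[0] == pytest.approx(1.0)

    def test_model_round_trip(self, tmp_path):
        m = random_model(3, seed=42)
        for name in ("m.json", "m.yaml"):
            save_model(m, tmp_path / name)
            m2 = load_model(tmp_path / name)
            np.testing.assert_allclose(m2.emission, m.emission, atol=1e-12)
            np.testing.assert_allclose(m2.transition, m.transition, atol=1e-12)
            assert m2.alphabet.codes == m.alphabet.codes

    def test_estimator_params_clone(self):
        from sklearn.base import clone

        est = HiddenMarkovGrammar(n_states=4, n_restarts=7, random_state=3)
        params = est.get_params()
        assert params["n_states"] == 4 and params["n_restarts"] == 7
        clone(est)  # sklearn-compatible constructor contract

    def test_order_scan_estimator(self):
        m = two_state_ab()
        X = [sample_from_hmm(m, 80, seed=i) for i in range(4)]
        scan = HmmOrderScan(min_states=1, max_states=3, n_restarts=5,
                            random_state=0).fit(X)
        assert scan.optimal_states_ in (2, 3)
        assert scan.best_model_.n_states == scan.optimal_states_
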