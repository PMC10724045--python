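"""Event-based model core: mixtures, likelihood, search, staging, bootstrap."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import kendalltau, spearmanr

import disconseq as dq
from disconseq import (
    EventProbabilities,
    GMMFit,
    bootstrap_sequences,
    event_probabilities,
    exhaustive_sequence,
    fit_gmm,
    optimize_sequence,
    randomness_test,
    sequence_loglikelihood,
    stage_subjects,
)


def brute_force_loglik(pe, pn, seq, prior):
    """Direct summation oracle for the staged-mixture likelihood."""
    total = 0.0
    n, p = pe.shape
    for i in range(n):
        s = 0.0
        for k in range(p + 1):
            term = prior[k]
            for pos in range(p):
                term *= pe[i, seq[pos]] if pos < k else pn[i, seq[pos]]
            s += term
        total += np.log(s)
    return total


def random_probs(rng, n, p):
    return EventProbabilities(rng.uniform(0.05, 0.95, (n, p)), rng.uniform(0.05, 0.95, (n, p)))


class TestFitGMM:
    def test_recovers_well_separated_components(self):
        rng = np.random.default_rng(0)
        n = 1000
        g = (rng.random(n) < 0.5).astype(int)
        x = np.where(g == 1, rng.normal(1.0, 0.05, n), rng.normal(0.0, 0.05, n))
        f = fit_gmm(x, g)
        assert abs(f.healthy_mean - 0.0) < 0.02
        assert abs(f.patho_mean - 1.0) < 0.02

    def test_identical_components_flagged_degenerate(self):
        rng = np.random.default_rng(1)
        n = 200
        x = rng.normal(0.5, 0.1, n)
        g = (rng.random(n) < 0.3).astype(int)
        f = fit_gmm(x, g)
        assert f.degenerate
        probs = event_probabilities(x[:, None], [f])
        # indistinguishable components: event and no-event likelihoods agree closely
        np.testing.assert_allclose(
            np.log(probs.p_event), np.log(probs.p_noevent), atol=0.5
        )

    def test_label_swap_leaves_ordered_fit_unchanged(self):
        rng = np.random.default_rng(2)
        n = 600
        g = (rng.random(n) < 0.4).astype(int)
        x = np.where(g == 1, rng.normal(0.8, 0.1, n), rng.normal(0.2, 0.1, n))
        f1 = fit_gmm(x, g)
        f2 = fit_gmm(x, 1 - g)
        assert abs(f1.healthy_mean - f2.healthy_mean) < 0.05
        assert abs(f1.patho_mean - f2.patho_mean) < 0.05

    def test_requires_both_groups(self):
        with pytest.raises(ValueError, match="both groups"):
            fit_gmm(np.random.default_rng(0).random(20), np.zeros(20))

    def test_ordering_invariant_enforced(self):
        rng = np.random.default_rng(3)
        n = 500
        # "group 1" actually sits lower: relabelling must still return patho >= healthy
        g = (rng.random(n) < 0.5).astype(int)
        x = np.where(g == 1, rng.normal(0.1, 0.05, n), rng.normal(0.9, 0.05, n))
        f = fit_gmm(x, g)
        assert f.patho_mean >= f.healthy_mean


class TestEventProbabilities:
    def test_matches_gaussian_closed_form(self):
        f = GMMFit(0.2, 0.1, 0.7, 0.2, 0.4)
        x = np.array([[0.2], [0.45], [0.9]])
        probs = event_probabilities(x, [f])
        for i, xi in enumerate(x[:, 0]):
            pe = np.exp(-0.5 * ((xi - 0.7) / 0.2) ** 2) / (0.2 * np.sqrt(2 * np.pi))
            pn = np.exp(-0.5 * ((xi - 0.2) / 0.1) ** 2) / (0.1 * np.sqrt(2 * np.pi))
            np.testing.assert_allclose(probs.p_event[i, 0], pe, rtol=1e-12)
            np.testing.assert_allclose(probs.p_noevent[i, 0], pn, rtol=1e-12)

    def test_healthy_value_far_from_patho(self):
        f = GMMFit(0.0, 0.01, 0.2, 0.01, 0.5)  # 20 sd separation
        probs = event_probabilities(np.array([[0.0]]), [f])
        assert probs.p_noevent[0, 0] > 1e6 * probs.p_event[0, 0]

    def test_floor_keeps_probabilities_positive(self):
        f = GMMFit(0.0, 0.01, 0.1, 0.01, 0.5)
        probs = event_probabilities(np.array([[50.0]]), [f])
        assert probs.p_event[0, 0] >= 1e-12 and probs.p_noevent[0, 0] >= 1e-12


class TestSequenceLoglikelihood:
    def test_uniform_probabilities_closed_form(self):
        rng = np.random.default_rng(0)
        for n, p in [(3, 2), (10, 4), (50, 6), (7, 1), (20, 5)]:
            probs = EventProbabilities(np.full((n, p), 0.5), np.full((n, p), 0.5))
            for _ in range(3):
                seq = rng.permutation(p)
                ll = sequence_loglikelihood(probs, seq)
                np.testing.assert_allclose(ll, n * p * np.log(0.5), rtol=1e-9)

    def test_single_region_two_term_sum(self):
        probs = EventProbabilities(np.array([[0.9]]), np.array([[0.2]]))
        ll = sequence_loglikelihood(probs, [0])
        np.testing.assert_allclose(ll, np.log(0.5 * 0.2 + 0.5 * 0.9), rtol=1e-12)

    def test_matches_bruteforce_all_permutations(self):
        rng = np.random.default_rng(1)
        pe = rng.uniform(0.1, 0.9, (2, 3))
        pn = rng.uniform(0.1, 0.9, (2, 3))
        probs = EventProbabilities(pe, pn)
        prior = np.full(4, 0.25)
        for perm in itertools.permutations(range(3)):
            np.testing.assert_allclose(
                sequence_loglikelihood(probs, perm, prior),
                brute_force_loglik(pe, pn, perm, prior),
                rtol=1e-10,
            )

    def test_unnormalized_prior_rejected(self):
        probs = random_probs(np.random.default_rng(0), 5, 3)
        with pytest.raises(ValueError, match="normalized"):
            sequence_loglikelihood(probs, [0, 1, 2], np.array([0.5, 0.5, 0.5, 0.5]))

    def test_equal_event_noevent_probs_sequence_invariant(self):
        rng = np.random.default_rng(2)
        pe = rng.uniform(0.1, 0.9, (20, 5))
        probs = EventProbabilities(pe, pe.copy())
        lls = [sequence_loglikelihood(probs, perm) for perm in itertools.permutations(range(5))]
        assert (max(lls) - min(lls)) <= 1e-9 * abs(lls[0])


class TestSequenceSearch:
    def test_exhaustive_single_region(self):
        probs = random_probs(np.random.default_rng(0), 10, 1)
        res = exhaustive_sequence(probs)
        assert res.sequence.tolist() == [0]

    def test_exhaustive_tie_break_lexicographic(self):
        probs = EventProbabilities(np.full((4, 3), 0.5), np.full((4, 3), 0.5))
        res = exhaustive_sequence(probs)
        assert res.sequence.tolist() == [0, 1, 2]

    def test_exhaustive_beats_random_permutations(self):
        rng = np.random.default_rng(3)
        probs = random_probs(rng, 30, 5)
        res = exhaustive_sequence(probs)
        for _ in range(200):
            assert res.log_likelihood >= sequence_loglikelihood(probs, rng.permutation(5)) - 1e-12

    def test_exhaustive_guard(self):
        probs = random_probs(np.random.default_rng(0), 5, 9)
        with pytest.raises(ValueError, match="P <= 8"):
            exhaustive_sequence(probs)

    @pytest.mark.parametrize("seed", range(20))
    def test_optimizer_attains_exhaustive_maximum(self, seed):
        rng = np.random.default_rng(seed)
        probs = random_probs(rng, 40, 5)
        ex = exhaustive_sequence(probs)
        opt = optimize_sequence(probs, n_restarts=10, seed=seed)
        np.testing.assert_allclose(opt.log_likelihood, ex.log_likelihood, rtol=1e-9)

    def test_optimizer_deterministic(self):
        probs = random_probs(np.random.default_rng(5), 50, 8)
        r1 = optimize_sequence(probs, n_restarts=5, seed=42)
        r2 = optimize_sequence(probs, n_restarts=5, seed=42)
        assert r1.sequence.tolist() == r2.sequence.tolist()
        assert r1.log_likelihood == r2.log_likelihood


class TestStaging:
    def test_rows_sum_to_one(self):
        probs = random_probs(np.random.default_rng(0), 25, 6)
        post = stage_subjects(probs, np.arange(6))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, rtol=1e-12)

    def test_all_healthy_subject_stages_at_zero(self):
        pe = np.full((1, 4), 1e-6)
        pn = np.ones((1, 4))
        post = stage_subjects(EventProbabilities(pe, pn), np.arange(4))
        assert post[0, 0] > 0.999

    def test_two_region_hand_computation(self):
        pe = np.array([[0.8, 0.3]])
        pn = np.array([[0.4, 0.9]])
        post = stage_subjects(EventProbabilities(pe, pn), [0, 1])
        terms = np.array([0.4 * 0.9, 0.8 * 0.9, 0.8 * 0.3]) / 3.0
        np.testing.assert_allclose(post[0], terms / terms.sum(), rtol=1e-12)


class TestRandomnessTest:
    def test_chance_frequencies_give_t_zero(self):
        p = 5
        pv = np.full((p, p), 1 / p)
        res = randomness_test(pv, np.arange(p))
        assert res.t == 0.0 and not res.degenerate

    def test_matches_one_sample_t_formula(self):
        freqs = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        p = 5
        pv = np.zeros((p, p))
        pv[np.arange(p), np.arange(p)] = freqs
        res = randomness_test(pv, np.arange(p))
        t_hand = (freqs.mean() - 1 / p) / (freqs.std(ddof=1) / np.sqrt(p))
        np.testing.assert_allclose(res.t, t_hand, rtol=1e-12)
        assert 0 < res.p_one_sided < 0.05

    def test_perfectly_stable_sequence_flagged_degenerate(self):
        pv = np.eye(4)
        res = randomness_test(pv, np.arange(4))
        assert res.degenerate and np.isinf(res.t) and res.p_one_sided == 0.0


class TestBootstrapSequences:
    def test_zero_noise_positional_variance_concentrated(self):
        cfg = dq.GeneratorConfig(
            n_subjects=60, n_regions=4, healthy_mean=0.1, healthy_sd=0.0,
            patho_mean=0.9, patho_sd=0.0, seed=0,
        )
        ids = dq.default_region_ids(4)
        seq = [ids[1], ids[3], ids[0], ids[2]]
        cohort, truth = dq.make_biomarker_cohort(cfg, seq)
        res = bootstrap_sequences(cohort.matrix, cohort.group_labels, n_boot=10, seed=0,
                                  n_restarts=5, region_ids=ids)
        np.testing.assert_allclose(res.positional_variance.sum(axis=1), 1.0)
        assert res.sequence_ids == seq
        # every bootstrap recovers the planted order exactly
        pos_of = {r: i for i, r in enumerate(seq)}
        for j, rid in enumerate(ids):
            assert res.positional_variance[j, pos_of[rid]] == 1.0

    def test_noise_rows_high_entropy_vs_signal(self, planted_cohort):
        cohort, truth = planted_cohort
        p = cohort.n_regions
        res_sig = bootstrap_sequences(cohort.matrix, cohort.group_labels, n_boot=15, seed=1,
                                      n_restarts=8, boot_restarts=2)
        cfg_noise = dq.GeneratorConfig(n_subjects=240, n_regions=p, patho_mean=0.05, seed=12)
        noise, _ = dq.make_biomarker_cohort(cfg_noise, dq.default_region_ids(p))
        res_noise = bootstrap_sequences(noise.matrix, noise.group_labels, n_boot=15, seed=1,
                                        n_restarts=8, boot_restarts=2)

        def mean_entropy(pv):
            q = np.clip(pv, 1e-12, 1)
            return float((-q * np.log(q)).sum(axis=1).mean())

        assert mean_entropy(res_noise.positional_variance) > mean_entropy(res_sig.positional_variance)
        assert mean_entropy(res_noise.positional_variance) > 0.6 * np.log(p)


class TestParameterRecovery:
    def test_planted_sequence_recovered_and_staging_consistent(self, planted_cohort):
        cohort, truth = planted_cohort
        ids = cohort.region_ids
        fit = dq.fit_event_model(cohort.matrix, cohort.group_labels, seed=0)
        tp = {r: i for i, r in enumerate(truth.sequence)}
        tau = kendalltau([tp[ids[j]] for j in fit.sequence], range(len(ids))).statistic
        assert tau >= 0.8
        post = stage_subjects(fit.probs, fit.sequence)
        mean_stage = post @ np.arange(post.shape[1])
        rho = spearmanr(mean_stage, truth.stages).statistic
        assert rho >= 0.8
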