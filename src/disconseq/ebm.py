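"""Discriminative event-based model of disconnection ordering.

An *event* is one region's disconnectivity leaving the healthy distribution
for the pathological one. For region ``p`` a two-component univariate Gaussian
mixture supplies the likelihoods ``P(x_pn | E_p)`` (value drawn from the
pathological component) and ``P(x_pn | not E_p)`` (healthy component). Given a
candidate event order ``S`` and a prior ``P(k)`` over the latent stage
``k`` (number of events that have already occurred), the data likelihood is

    P(X | S) = prod_n  sum_{k=0}^{P}  P(k)
               * prod_{p <= k} P(x_{S(p)n} | E)
               * prod_{p >  k} P(x_{S(p)n} | not E)

The maximum-likelihood order is found by greedy pairwise-swap ascent from
multiple random starts (an exhaustive enumerator is provided as an oracle for
small P). Uncertainty comes from refitting the whole model on stratified
bootstrap resamples: the positional-variance matrix records how often each
region lands at each position, and each region's event centre is its mean
bootstrap position with a bootstrap standard error.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "GMMFit",
    "EventProbabilities",
    "EventModelFit",
    "SequenceResult",
    "fit_gmm",
    "fit_event_model",
    "event_probabilities",
    "uniform_stage_prior",
    "sequence_loglikelihood",
    "exhaustive_sequence",
    "optimize_sequence",
    "stage_subjects",
    "bootstrap_sequences",
    "randomness_test",
    "RandomnessResult",
]

PROB_FLOOR = 1e-12


# --------------------------------------------------------------------------
# Gaussian mixture per region
# --------------------------------------------------------------------------

@dataclass
class GMMFit:
    """Two-component Gaussian mixture for one region's biomarker.

    The pathological component has the larger mean (disconnection only
    increases with pathology); ``patho_weight`` is its mixing proportion.
    """

    healthy_mean: float
    healthy_sd: float
    patho_mean: float
    patho_sd: float
    patho_weight: float
    converged: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.healthy_sd <= 0 or self.patho_sd <= 0:
            raise ValueError("component sds must be positive")
        if not 0.0 < self.patho_weight < 1.0:
            raise ValueError("patho_weight must lie in (0, 1)")
        if self.patho_mean < self.healthy_mean:
            raise ValueError("pathological mean must be >= healthy mean")


def _norm_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


def fit_gmm(
    values: np.ndarray,
    group_labels,
    max_iter: int = 2000,
    tol: float = 1e-7,
    sd_floor_frac: float = 1e-3,
    tied_sd: bool = True,
) -> GMMFit:
    """EM fit of a two-component mixture on one region's pooled values.

    Initialization is group-informed: group 0 seeds the healthy component,
    group 1 the pathological one, and the initial pathological weight is the
    group-1 fraction. The mixture — not the label — decides final membership,
    since mildly impaired subjects may already harbour events.

    By default the two components share one variance (``tied_sd=True``).
    Unconstrained univariate two-component mixtures are weakly identified on
    a few hundred observations: the likelihood rewards collapsing one narrow
    component onto a sub-cluster of the dominant mode, which wrecks the event
    probabilities for regions whose true pathological fraction is near 0 or 1.
    Tying the variances (the homoscedastic model, as in mclust's "E" family)
    removes that failure mode at the cost of some flexibility.

    Component sds are floored at ``sd_floor_frac`` times the column SD. If EM
    fails to converge within ``max_iter`` iterations the initialization fit
    is returned with ``converged=False``.
    """
    x = np.asarray(values, dtype=float).ravel()
    g = np.asarray(group_labels, dtype=int).ravel()
    if len(x) != len(g):
        raise ValueError("values and group labels differ in length")
    if len(x) < 10:
        raise ValueError("need at least 10 subjects to fit a mixture")
    if not (np.any(g == 0) and np.any(g == 1)):
        raise ValueError("both groups must be present")

    col_sd = x.std()
    sd_min = sd_floor_frac * (col_sd if col_sd > 0 else 1.0)

    def grp_stats(mask):
        v = x[mask]
        return float(v.mean()), max(float(v.std()), sd_min)

    mu_h, sd_h = grp_stats(g == 0)
    mu_p, sd_p = grp_stats(g == 1)
    w = float(np.clip(np.mean(g), 1e-3, 1 - 1e-3))
    init = (mu_h, sd_h, mu_p, sd_p, w)

    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        lh = np.log1p(-w) + _norm_logpdf(x, mu_h, sd_h)
        lp = np.log(w) + _norm_logpdf(x, mu_p, sd_p)
        norm = np.logaddexp(lh, lp)
        ll = float(norm.sum())
        resp_p = np.exp(lp - norm)  # responsibility of pathological component
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll
        wp = resp_p.sum()
        wh = len(x) - wp
        if wp < 1e-10 or wh < 1e-10:  # one component vanished
            break
        mu_p = float(resp_p @ x / wp)
        mu_h = float((1 - resp_p) @ x / wh)
        if tied_sd:
            pooled = float(
                np.sqrt((resp_p @ (x - mu_p) ** 2 + (1 - resp_p) @ (x - mu_h) ** 2) / len(x))
            )
            sd_p = sd_h = max(pooled, sd_min)
        else:
            sd_p = max(float(np.sqrt(resp_p @ (x - mu_p) ** 2 / wp)), sd_min)
            sd_h = max(float(np.sqrt((1 - resp_p) @ (x - mu_h) ** 2 / wh)), sd_min)
        w = float(np.clip(wp / len(x), 1e-3, 1 - 1e-3))

    if not converged:
        mu_h, sd_h, mu_p, sd_p, w = init
    if mu_p < mu_h:  # relabel so pathology is the upper component
        mu_h, sd_h, mu_p, sd_p = mu_p, sd_p, mu_h, sd_h
        w = 1.0 - w
    # separation below ~0.2 pooled SD is within sampling noise of identical
    # components at cohort-scale n; flag as near-degenerate
    degenerate = (mu_p - mu_h) <= 0.2 * 0.5 * (sd_h + sd_p)
    return GMMFit(mu_h, sd_h, mu_p, sd_p, float(np.clip(w, 1e-3, 1 - 1e-3)),
                  converged=converged, degenerate=degenerate)


# --------------------------------------------------------------------------
# Event probabilities and the sequence likelihood
# --------------------------------------------------------------------------

@dataclass
class EventProbabilities:
    """Per-subject, per-region likelihoods under the event / no-event densities.

    Both matrices are floored at a tiny constant so log-space arithmetic stays
    finite even for extreme outliers.
    """

    p_event: np.ndarray
    p_noevent: np.ndarray

    def __post_init__(self) -> None:
        self.p_event = np.asarray(self.p_event, dtype=float)
        self.p_noevent = np.asarray(self.p_noevent, dtype=float)
        if self.p_event.shape != self.p_noevent.shape or self.p_event.ndim != 2:
            raise ValueError("p_event and p_noevent must be equal-shape N x P matrices")
        if (self.p_event <= 0).any() or (self.p_noevent <= 0).any():
            raise ValueError("likelihoods must be strictly positive (floored)")
        self.log_event = np.log(self.p_event)
        self.log_noevent = np.log(self.p_noevent)

    @property
    def n_subjects(self) -> int:
        return self.p_event.shape[0]

    @property
    def n_regions(self) -> int:
        return self.p_event.shape[1]


def event_probabilities(matrix: np.ndarray, fits: Sequence[GMMFit], floor: float = PROB_FLOOR) -> EventProbabilities:
    """Evaluate each region's fitted component densities at the observed values."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] != len(fits):
        raise ValueError(f"{len(fits)} fits for {X.shape[1]} regions")
    pe = np.empty_like(X)
    pn = np.empty_like(X)
    for j, f in enumerate(fits):
        pe[:, j] = np.exp(_norm_logpdf(X[:, j], f.patho_mean, f.patho_sd))
        pn[:, j] = np.exp(_norm_logpdf(X[:, j], f.healthy_mean, f.healthy_sd))
    return EventProbabilities(np.maximum(pe, floor), np.maximum(pn, floor))


def uniform_stage_prior(n_regions: int) -> np.ndarray:
    return np.full(n_regions + 1, 1.0 / (n_regions + 1))


def _check_prior(stage_prior, n_regions: int) -> np.ndarray:
    if stage_prior is None:
        return uniform_stage_prior(n_regions)
    prior = np.asarray(stage_prior, dtype=float)
    if prior.shape != (n_regions + 1,):
        raise ValueError(f"stage prior must have length P+1 = {n_regions + 1}")
    if (prior < 0).any() or abs(prior.sum() - 1.0) > 1e-8:
        raise ValueError("stage prior must be a normalized distribution over {0..P}")
    return prior


def _check_sequence(sequence, n_regions: int) -> np.ndarray:
    seq = np.asarray(sequence, dtype=int)
    if sorted(seq.tolist()) != list(range(n_regions)):
        raise ValueError("sequence must be a permutation of the region column indices")
    return seq


def _stage_log_terms(probs: EventProbabilities, seq: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """(N, P+1) matrix of log [ P(k) * prod_{p<=k} pe * prod_{p>k} pn ]."""
    n = probs.n_subjects
    la = probs.log_event[:, seq]
    lb = probs.log_noevent[:, seq]
    zeros = np.zeros((n, 1))
    csa = np.concatenate([zeros, np.cumsum(la, axis=1)], axis=1)
    csb = np.concatenate([zeros, np.cumsum(lb, axis=1)], axis=1)
    with np.errstate(divide="ignore"):
        log_prior = np.log(prior)
    return log_prior[None, :] + csa + (csb[:, -1:] - csb)


def sequence_loglikelihood(probs: EventProbabilities, sequence, stage_prior=None) -> float:
    """Total log-likelihood of the data under a candidate event order,
    marginalizing each subject's latent stage (computed stably in log space)."""
    seq = _check_sequence(sequence, probs.n_regions)
    prior = _check_prior(stage_prior, probs.n_regions)
    terms = _stage_log_terms(probs, seq, prior)
    return float(logsumexp(terms, axis=1).sum())


def stage_subjects(probs: EventProbabilities, sequence, stage_prior=None) -> np.ndarray:
    """Posterior distribution over stages k = 0..P for each subject; rows sum to 1."""
    seq = _check_sequence(sequence, probs.n_regions)
    prior = _check_prior(stage_prior, probs.n_regions)
    terms = _stage_log_terms(probs, seq, prior)
    terms -= logsumexp(terms, axis=1, keepdims=True)
    return np.exp(terms)


# --------------------------------------------------------------------------
# Sequence search
# --------------------------------------------------------------------------

@dataclass
class SequenceResult:
    """Estimated event order with optional bootstrap uncertainty.

    ``sequence`` holds region column indices, earliest event first;
    ``positional_variance[r, j]`` is the fraction of bootstraps in which
    region ``r`` occupied position ``j`` (0-based); ``event_centres`` are mean
    bootstrap positions (1-based) with standard errors ``event_centre_se``.
    """

    sequence: np.ndarray
    log_likelihood: float
    region_ids: list[str] | None = None
    positional_variance: np.ndarray | None = None
    event_centres: np.ndarray | None = None
    event_centre_se: np.ndarray | None = None
    n_boot: int | None = None
    model: object | None = None  # full-data EventModelFit, when available

    def __post_init__(self) -> None:
        self.sequence = np.asarray(self.sequence, dtype=int)

    @property
    def sequence_ids(self) -> list[str]:
        ids = self.region_ids or [str(j) for j in range(len(self.sequence))]
        return [ids[j] for j in self.sequence]

    def as_dict(self) -> dict:
        d = {
            "sequence": self.sequence_ids,
            "log_likelihood": self.log_likelihood,
        }
        if self.event_centres is not None:
            ids = self.region_ids or [str(j) for j in range(len(self.sequence))]
            d["event_centres"] = {ids[j]: float(self.event_centres[j]) for j in range(len(ids))}
            d["event_centre_se"] = {ids[j]: float(self.event_centre_se[j]) for j in range(len(ids))}
            d["n_boot"] = self.n_boot
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1, sort_keys=True)

    def positional_variance_frame(self) -> pd.DataFrame:
        if self.positional_variance is None:
            raise ValueError("no bootstrap positional variance available")
        ids = self.region_ids or [str(j) for j in range(len(self.sequence))]
        return pd.DataFrame(
            self.positional_variance,
            index=pd.Index(ids, name="region_id"),
            columns=[f"pos_{j + 1}" for j in range(self.positional_variance.shape[1])],
        )


def exhaustive_sequence(probs: EventProbabilities, stage_prior=None) -> SequenceResult:
    """Enumerate every permutation (oracle; guarded to P <= 8).

    Ties are broken toward the lexicographically first permutation, which is
    visited first by ``itertools.permutations``.
    """
    p = probs.n_regions
    if p > 8:
        raise ValueError("exhaustive search is limited to P <= 8")
    prior = _check_prior(stage_prior, p)
    best_seq, best_ll = None, -np.inf
    for perm in itertools.permutations(range(p)):
        ll = sequence_loglikelihood(probs, perm, prior)
        if ll > best_ll:
            best_seq, best_ll = perm, ll
    return SequenceResult(np.asarray(best_seq), best_ll)


def _greedy_ascent(probs, prior, seq: np.ndarray) -> tuple[np.ndarray, float]:
    """Steepest-ascent pairwise swaps until no swap improves the likelihood.

    Swapping positions i < j only adds ``delta = log pe/pn (region j) -
    log pe/pn (region i)`` to the stage terms for k in (i, j], so each sweep
    scores all P(P-1)/2 swaps from prefix/suffix log-sum-exps of the current
    stage-term matrix in O(N P^2) rather than re-evaluating from scratch.
    """
    seq = seq.copy()
    p = len(seq)
    ll = sequence_loglikelihood(probs, seq, prior)
    delta_all = probs.log_event - probs.log_noevent
    while True:
        terms = _stage_log_terms(probs, seq, prior)  # (N, P+1)
        # prefix[k] = lse(terms[:, :k]); suffix[k] = lse(terms[:, k:])
        n = terms.shape[0]
        neg = np.full(n, -np.inf)
        prefix = np.empty((p + 2, n))
        suffix = np.empty((p + 2, n))
        prefix[0] = neg
        for k in range(p + 1):
            prefix[k + 1] = np.logaddexp(prefix[k], terms[:, k])
        suffix[p + 1] = neg
        for k in range(p, -1, -1):
            suffix[k] = np.logaddexp(suffix[k + 1], terms[:, k])
        d = delta_all[:, seq]  # (N, P)
        best_gain, best_pair = 1e-10, None
        for i in range(p - 1):
            block = neg  # lse of terms[:, i+1 .. j]
            for j in range(i + 1, p):
                block = np.logaddexp(block, terms[:, j])
                outside = np.logaddexp(prefix[i + 1], suffix[j + 1])
                shift = d[:, j] - d[:, i]
                cand = np.logaddexp(outside, block + shift).sum()
                if cand - ll > best_gain:
                    best_gain, best_pair = cand - ll, (i, j)
        if best_pair is None:
            return seq, ll
        i, j = best_pair
        seq[i], seq[j] = seq[j], seq[i]
        ll = sequence_loglikelihood(probs, seq, prior)


def optimize_sequence(
    probs: EventProbabilities,
    stage_prior=None,
    n_restarts: int = 25,
    seed: int | None = None,
    init=None,
) -> SequenceResult:
    """Maximize the sequence likelihood by greedy pairwise-swap ascent from
    ``n_restarts`` random starting permutations (plus an optional warm start).

    Deterministic given ``seed``; across restarts, ties in log-likelihood
    break toward the first-found, then lexicographically smaller, sequence.
    """
    p = probs.n_regions
    prior = _check_prior(stage_prior, p)
    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(_check_sequence(init, p))
    starts.extend(rng.permutation(p) for _ in range(n_restarts))
    if not starts:
        raise ValueError("need at least one restart or an init sequence")

    best_seq, best_ll = None, -np.inf
    for s in starts:
        seq, ll = _greedy_ascent(probs, prior, np.asarray(s, dtype=int))
        if ll > best_ll + 1e-10 or (
            best_seq is not None and abs(ll - best_ll) <= 1e-10 and tuple(seq) < tuple(best_seq)
        ):
            best_seq, best_ll = seq, ll
    return SequenceResult(best_seq, best_ll)


# --------------------------------------------------------------------------
# Joint event-model fitting
# --------------------------------------------------------------------------

def _fit_all(matrix: np.ndarray, group_labels) -> tuple[list[GMMFit], EventProbabilities]:
    fits = [fit_gmm(matrix[:, j], group_labels) for j in range(matrix.shape[1])]
    return fits, event_probabilities(matrix, fits)


def _pooled_shared_fit(matrix: np.ndarray, group_labels) -> list[GMMFit]:
    """Initial per-region mixtures that borrow strength across regions.

    Each column is z-scored and all N x P standardized values are pooled into
    one tied-variance two-component mixture whose mixing weights differ by
    group (the more-impaired group carries more pathological mass). A single
    region's marginal mixture is barely identified when the components
    overlap; the pooled fit pins a shared component geometry which is then
    mapped back to every column's original scale. These fits are
    initialization only — the staged refinement re-estimates each region.
    """
    X = np.asarray(matrix, dtype=float)
    g = np.asarray(group_labels, dtype=int)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = ((X - mu) / sd).ravel()
    gg = np.repeat(g, X.shape[1])

    mu_h, mu_p = float(z[gg == 0].mean()), float(z[gg == 1].mean())
    if mu_p - mu_h < 0.1:  # groups nearly coincide in z units: break symmetry
        mu_h, mu_p = -0.3, 0.3
    s, w0, w1 = 1.0, 0.3, 0.7
    ll_old = -np.inf
    for _ in range(500):
        wn = np.where(gg == 1, w1, w0)
        lh = np.log1p(-wn) + _norm_logpdf(z, mu_h, s)
        lp = np.log(wn) + _norm_logpdf(z, mu_p, s)
        norm = np.logaddexp(lh, lp)
        ll = float(norm.sum())
        resp = np.exp(lp - norm)
        if abs(ll - ll_old) < 1e-8 * (abs(ll) + 1.0):
            break
        ll_old = ll
        wp = resp.sum()
        wh = len(z) - wp
        if wp < 1e-8 or wh < 1e-8:
            break
        mu_p = float(resp @ z / wp)
        mu_h = float((1 - resp) @ z / wh)
        s = max(float(np.sqrt((resp @ (z - mu_p) ** 2 + (1 - resp) @ (z - mu_h) ** 2) / len(z))), 1e-3)
        w0 = float(np.clip(resp[gg == 0].mean(), 1e-3, 1 - 1e-3))
        w1 = float(np.clip(resp[gg == 1].mean(), 1e-3, 1 - 1e-3))
    if mu_p < mu_h:
        mu_h, mu_p = mu_p, mu_h
    w_pool = float(np.clip(np.mean(gg) * w1 + (1 - np.mean(gg)) * w0, 1e-3, 1 - 1e-3))
    return [
        GMMFit(
            healthy_mean=float(mu[j] + sd[j] * mu_h),
            healthy_sd=float(max(sd[j] * s, 1e-9)),
            patho_mean=float(mu[j] + sd[j] * mu_p),
            patho_sd=float(max(sd[j] * s, 1e-9)),
            patho_weight=w_pool,
        )
        for j in range(X.shape[1])
    ]


def _refit_from_staging(
    matrix: np.ndarray, probs: EventProbabilities, seq: np.ndarray, prior: np.ndarray
) -> list[GMMFit]:
    """EM step for the joint model: per-region component refit using event
    responsibilities implied by each subject's staging posterior.

    Under the model, region at position ``pos`` has had its event iff the
    subject's stage k >= pos, so gamma[n, p] = P(k >= pos_p | x_n) — the
    correct E-step — aggregates evidence from every region, which is what
    identifies overlapping components a single column cannot.
    """
    X = np.asarray(matrix, dtype=float)
    terms = _stage_log_terms(probs, np.asarray(seq), prior)
    post = np.exp(terms - logsumexp(terms, axis=1, keepdims=True))
    p = X.shape[1]
    pos = np.empty(p, dtype=int)
    pos[np.asarray(seq)] = np.arange(p)
    tail = np.cumsum(post[:, ::-1], axis=1)[:, ::-1]  # tail[:, k] = P(stage >= k)
    gamma = np.clip(tail[:, pos + 1], 1e-6, 1 - 1e-6)
    fits = []
    for j in range(p):
        x = X[:, j]
        r = gamma[:, j]
        sd_min = 1e-3 * (x.std() or 1.0)
        wp = r.sum()
        mu_p = float(r @ x / wp)
        mu_h = float((1 - r) @ x / (len(x) - wp))
        s = max(float(np.sqrt((r @ (x - mu_p) ** 2 + (1 - r) @ (x - mu_h) ** 2) / len(x))), sd_min)
        if mu_p < mu_h:
            mu_h, mu_p = mu_p, mu_h
        fits.append(GMMFit(mu_h, s, mu_p, s, float(np.clip(wp / len(x), 1e-3, 1 - 1e-3))))
    return fits


@dataclass
class EventModelFit:
    """Jointly fitted event model: sequence, per-region mixtures, likelihood."""

    sequence: np.ndarray
    log_likelihood: float
    fits: list[GMMFit]
    probs: EventProbabilities
    n_refinements: int


def fit_event_model(
    matrix: np.ndarray,
    group_labels,
    seed: int | None = None,
    n_restarts: int = 25,
    refine_rounds: int = 8,
    refine_restarts: int = 5,
    stage_prior=None,
    init=None,
) -> EventModelFit:
    """Fit mixtures and the event sequence by coordinate ascent on the joint
    staged-mixture likelihood.

    Pooled shared-component fits initialize the per-region mixtures; the
    sequence is optimized by greedy swap ascent; then mixture refits from the
    staging posterior alternate with warm-started sequence re-optimization
    until the sequence is stable or ``refine_rounds`` is reached. ``init``
    supplies a warm-start sequence (used by the bootstrap), skipping the
    expensive cold search.
    """
    X = np.asarray(matrix, dtype=float)
    g = np.asarray(group_labels, dtype=int)
    p = X.shape[1]
    prior = _check_prior(stage_prior, p)
    rng = np.random.default_rng(seed)

    fits = _pooled_shared_fit(X, g)
    probs = event_probabilities(X, fits)
    if init is not None:
        res = optimize_sequence(probs, prior, n_restarts=refine_restarts,
                                seed=int(rng.integers(2**31 - 1)), init=init)
    else:
        res = optimize_sequence(probs, prior, n_restarts=n_restarts,
                                seed=int(rng.integers(2**31 - 1)))
    seq = res.sequence
    prev = None
    rounds = 0
    for rounds in range(1, refine_rounds + 1):
        fits = _refit_from_staging(X, probs, seq, prior)
        probs = event_probabilities(X, fits)
        res = optimize_sequence(probs, prior, n_restarts=refine_restarts,
                                seed=int(rng.integers(2**31 - 1)), init=seq)
        seq = res.sequence
        if prev is not None and np.array_equal(prev, seq):
            break
        prev = seq.copy()
    return EventModelFit(seq, res.log_likelihood, fits, probs, rounds)


# --------------------------------------------------------------------------
# Bootstrap uncertainty
# --------------------------------------------------------------------------


def bootstrap_sequences(
    matrix: np.ndarray,
    group_labels,
    n_boot: int = 100,
    seed: int | None = None,
    n_restarts: int = 25,
    boot_restarts: int = 2,
    stage_prior=None,
    region_ids=None,
) -> SequenceResult:
    """Full-data maximum-likelihood sequence plus bootstrap uncertainty.

    The full data set yields the reported sequence. Each of ``n_boot``
    stratified resamples (with replacement, within group) refits every
    region's mixture and re-optimizes the order, warm-started from the
    full-data sequence with ``boot_restarts`` extra random restarts. Every
    row of the positional-variance matrix sums to 1.
    """
    X = np.asarray(matrix, dtype=float)
    g = np.asarray(group_labels, dtype=int)
    n, p = X.shape
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    prior = _check_prior(stage_prior, p)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_boot + 1)

    final = fit_event_model(X, g, seed=int(sub_seeds[0]), n_restarts=n_restarts,
                            refine_restarts=boot_restarts, stage_prior=prior)

    idx0, idx1 = np.flatnonzero(g == 0), np.flatnonzero(g == 1)
    positions = np.empty((n_boot, p), dtype=int)  # positions[b, r]: 0-based slot of region r
    for b in range(n_boot):
        rows = np.concatenate(
            [rng.choice(idx0, size=len(idx0), replace=True),
             rng.choice(idx1, size=len(idx1), replace=True)]
        )
        fit_b = fit_event_model(
            X[rows], g[rows], seed=int(sub_seeds[b + 1]), refine_rounds=4,
            refine_restarts=boot_restarts, stage_prior=prior, init=final.sequence,
        )
        positions[b, fit_b.sequence] = np.arange(p)

    pv = np.zeros((p, p))
    for j in range(p):
        pv[:, j] = (positions == j).mean(axis=0)
    centres = positions.mean(axis=0) + 1.0
    if n_boot > 1:
        se = positions.std(axis=0, ddof=1) / np.sqrt(n_boot)
    else:
        se = np.zeros(p)
    return SequenceResult(
        sequence=final.sequence,
        log_likelihood=final.log_likelihood,
        region_ids=list(region_ids) if region_ids is not None else None,
        positional_variance=pv,
        event_centres=centres,
        event_centre_se=se,
        n_boot=n_boot,
        model=final,
    )


# --------------------------------------------------------------------------
# Randomness test
# --------------------------------------------------------------------------

class RandomnessResult(NamedTuple):
    t: float
    p_one_sided: float
    p_two_sided: float
    frequencies: np.ndarray
    degenerate: bool


def randomness_test(positional_variance: np.ndarray, final_sequence) -> RandomnessResult:
    """Is the estimated order better than chance?

    For each region, take the fraction of bootstraps in which it occupied its
    final-sequence position, and compare these P frequencies against the
    chance level 1/P with a one-sample Student t-test. Reported one-sided for
    mean frequency > 1/P alongside the two-sided p. All-equal frequencies at
    exactly 1/P give t = 0; all-equal frequencies elsewhere (zero variance)
    are flagged degenerate with infinite t.
    """
    pv = np.asarray(positional_variance, dtype=float)
    p = pv.shape[0]
    if p < 2 or pv.shape != (p, p):
        raise ValueError("positional variance must be a P x P matrix with P >= 2")
    seq = _check_sequence(final_sequence, p)
    pos_of = np.empty(p, dtype=int)
    pos_of[seq] = np.arange(p)
    freqs = pv[np.arange(p), pos_of]
    null = 1.0 / p
    if freqs.std(ddof=1) == 0:
        m = freqs.mean()
        if np.isclose(m, null):
            return RandomnessResult(0.0, 0.5, 1.0, freqs, False)
        t = np.inf if m > null else -np.inf
        return RandomnessResult(t, 0.0 if m > null else 1.0, 0.0, freqs, True)
    t, p_two = stats.ttest_1samp(freqs, null)
    t = float(t)
    p_two = float(p_two)
    p_one = p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
    return RandomnessResult(t, p_one, p_two, freqs, False)
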