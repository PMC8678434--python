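"""Affinity propagation exemplar clustering, implemented from scratch.

Similarities are negative powered Euclidean distances, S[i,k] = −d(i,k)^r
with r = 2 by default (negative squared distance). The shared diagonal
"preference" controls how readily points become exemplars; it is set to a
quantile q of the off-diagonal similarities, with q = 0 (the minimum)
favouring the fewest clusters. The algorithm exchanges responsibility and
availability messages until the exemplar set is stable, approximately
maximising the net similarity

    sum_{i not in E} max_{k in E} S[i,k]  +  sum_{k in E} preference[k].

A brute-force enumeration of exemplar subsets (feasible for n <= 12)
provides the exact optimum for validation.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class APConfig:
    """Tuning knobs for the message-passing loop.

    damping is the fraction of the previous message kept at each update
    (0.5 <= damping < 1); the loop stops once the exemplar set has been
    unchanged for ``convergence_window`` consecutive iterations, or at
    ``max_iterations``. ``tie_noise_scale`` scales a one-off seeded jitter
    (times the range of S) that breaks exact ties from duplicate rows; set
    it to 0 to disable.
    """

    q: float = 0.0
    damping: float = 0.9
    max_iterations: int = 1000
    convergence_window: int = 100
    tie_noise_scale: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.damping < 1.0:
            raise ValueError("damping must be in [0.5, 1)")
        if self.convergence_window < 1:
            raise ValueError("convergence_window must be >= 1")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("preference quantile q must be in [0, 1]")


@dataclass
class APResult:
    exemplars: list[int]
    labels: np.ndarray
    n_iterations: int
    converged: bool
    net_similarity: float
    preference: float


def build_similarity(X: np.ndarray, r: float = 2.0) -> np.ndarray:
    """Pairwise similarity S[i,k] = −(Euclidean distance)^r, diagonal NaN
    (unset until a preference is applied)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D array")
    if np.isnan(X).any():
        raise ValueError(
            "feature matrix contains missing values; restrict to complete "
            "cases (eligibility_filter) before building similarities"
        )
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
    # guard tiny negative round-off before the fractional power
    dist = np.sqrt(np.maximum(sq, 0.0))
    S = -(dist**r)
    np.fill_diagonal(S, np.nan)
    return S


def preference_from_quantile(S: np.ndarray, q: float = 0.0) -> float:
    """The q-th quantile (linear interpolation) of the off-diagonal
    similarities; q = 0 is the minimum, q = 1 the maximum."""
    if S.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    off = S[~np.eye(S.shape[0], dtype=bool)]
    return float(np.quantile(off, q))


def apply_preference(S: np.ndarray, preference: float) -> np.ndarray:
    out = S.copy()
    np.fill_diagonal(out, preference)
    return out


def net_similarity(S: np.ndarray, exemplars: list[int]) -> float:
    """Objective value of an exemplar set on a similarity matrix whose
    diagonal holds the preferences."""
    n = S.shape[0]
    E = sorted(exemplars)
    total = sum(float(S[k, k]) for k in E)
    non = [i for i in range(n) if i not in set(E)]
    if non:
        total += float(S[np.ix_(non, E)].max(axis=1).sum())
    return total


def run_affinity_propagation(S: np.ndarray, config: APConfig = APConfig()) -> APResult:
    """Run damped responsibility/availability message passing on a
    similarity matrix whose diagonal already carries the preference.

    Ends when the exemplar set has been stable for ``convergence_window``
    iterations (converged) or at ``max_iterations`` (flagged unconverged;
    if no exemplar has emerged the point with the largest responsibility +
    availability self-evidence is returned as a best-effort single
    exemplar). Each point is labelled with its most similar exemplar;
    exemplars label themselves.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.ndim != 2 or S.shape[1] != n:
        raise ValueError("S must be square")
    if np.isnan(S).any() or np.isinf(S).any():
        raise ValueError("S must be finite (did you apply a preference?)")
    if n == 1:
        return APResult([0], np.zeros(1, dtype=int), 0, True, float(S[0, 0]), float(S[0, 0]))

    preference = float(np.diag(S).mean())
    S_orig = S
    spread = float(S.max() - S.min())
    if config.tie_noise_scale > 0 and spread > 0:
        # all-equal S has no ties worth breaking; jitter would only
        # manufacture spurious exemplars
        rng = np.random.default_rng(config.seed)
        S = S + config.tie_noise_scale * spread * rng.standard_normal(S.shape)

    lam = config.damping
    R = np.zeros_like(S)
    A = np.zeros_like(S)
    idx = np.arange(n)
    exemplars: list[int] = []
    stable = 0
    iteration = 0
    converged = False

    for iteration in range(1, config.max_iterations + 1):
        # responsibilities: r(i,k) = S(i,k) - max_{k' != k} [a(i,k') + S(i,k')]
        AS = A + S
        first_k = AS.argmax(axis=1)
        first = AS[idx, first_k]
        AS[idx, first_k] = -np.inf
        second = AS.max(axis=1)
        AS[idx, first_k] = first
        Rnew = S - first[:, None]
        Rnew[idx, first_k] = S[idx, first_k] - second
        R = lam * R + (1 - lam) * Rnew

        # availabilities: a(i,k) = min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, 0.0)
        colsum = Rp.sum(axis=0) + np.diag(R)
        Anew = np.minimum(0.0, colsum[None, :] - Rp)
        np.fill_diagonal(Anew, colsum - np.diag(R))
        A = lam * A + (1 - lam) * Anew

        current = list(np.flatnonzero(np.diag(R) + np.diag(A) > 0))
        if current and current == exemplars:
            stable += 1
            if stable >= config.convergence_window:
                converged = True
                break
        else:
            stable = 1 if current else 0
        exemplars = current

    if not exemplars:
        exemplars = [int(np.argmax(np.diag(R) + np.diag(A)))]
        converged = False

    # final refinement (standard): within each cluster, promote the member
    # maximising the intra-cluster similarity sum, then reassign
    assign = np.asarray(exemplars)[S_orig[:, exemplars].argmax(axis=1)]
    assign[exemplars] = exemplars
    refined = []
    for k in exemplars:
        members = np.flatnonzero(assign == k)
        sub = S_orig[np.ix_(members, members)].copy()
        np.fill_diagonal(sub, 0.0)
        refined.append(int(members[sub.sum(axis=0).argmax()]))
    exemplars = sorted(set(refined))

    labels_pos = S_orig[:, exemplars].argmax(axis=1)
    labels = np.asarray([exemplars[j] for j in labels_pos], dtype=int)
    labels[exemplars] = exemplars
    return APResult(
        exemplars=sorted(int(e) for e in exemplars),
        labels=labels,
        n_iterations=iteration,
        converged=converged,
        net_similarity=net_similarity(S_orig, exemplars),
        preference=preference,
    )


def brute_force_exemplar_oracle(S: np.ndarray) -> tuple[list[int], float]:
    """Exact maximiser of the net-similarity objective by enumerating all
    non-empty exemplar subsets; ties break to the lexicographically
    smallest set. Refuses n > 12 (2^n enumeration)."""
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if n > 12:
        raise ValueError("brute-force oracle limited to n <= 12")
    best_score = -np.inf
    best_combo: tuple[int, ...] | None = None
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            score = net_similarity(S, list(combo))
            if score > best_score or (
                score == best_score and (best_combo is None or combo < best_combo)
            ):
                best_score, best_combo = score, combo
    assert best_combo is not None
    return list(best_combo), float(best_score)


def cluster_feature_matrix(
    X: np.ndarray, config: APConfig = APConfig(), r: float = 2.0
) -> APResult:
    """Convenience wrapper: similarities from rows of X, preference from the
    configured quantile, then message passing."""
    S = build_similarity(X, r=r)
    pref = preference_from_quantile(S, config.q)
    return run_affinity_propagation(apply_preference(S, pref), config)
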