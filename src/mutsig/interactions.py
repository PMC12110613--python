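"""Pairwise co-occurrence / mutual-exclusivity analysis of signature presence.

Given a binary samples x groups presence matrix, every unordered pair of
groups is scored with the exact hypergeometric test on the 2x2 overlap
table: with X ~ Hypergeometric(N, n_a, n_b) and observed overlap k,

    p_co = P(X >= k)   (co-occurrence, upper tail)
    p_ex = P(X <= k)   (mutual exclusivity, lower tail)

Both tails include P(X = k), the standard exact-test convention, so
p_co + p_ex >= 1. The smaller tail nominates the candidate direction; after
multiple-testing adjustment across all tested pairs (Benjamini-Hochberg by
default, or none to call on raw p), the direction is set when the winning
q-value is at most alpha. Pairs where either group is never present are
reported untestable rather than given p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class UntestablePairError(ValueError):
    """A pair with a zero presence margin has no defined test."""


@dataclass
class InteractionResult:
    group_a: str
    group_b: str
    N: int
    n_a: int
    n_b: int
    k: int
    p_co: float
    p_ex: float
    q: float
    direction: str  # {co-occurring, exclusive, none, untestable}


def hypergeom_tails(N: int, n_a: int, n_b: int, k: int) -> tuple[float, float]:
    """Exact upper and lower tail probabilities of the overlap count.

    Computed by log-space summation of the hypergeometric pmf over the
    support, so extreme tails keep full relative precision.
    """
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValueError("margins must lie in [0, N]")
    if n_a == 0 or n_b == 0:
        raise UntestablePairError("zero presence margin: test undefined")
    k_min = max(0, n_a + n_b - N)
    k_max = min(n_a, n_b)
    if not k_min <= k <= k_max:
        raise ValueError(f"overlap {k} outside support [{k_min}, {k_max}]")
    support = np.arange(k_min, k_max + 1)
    logpmf = hypergeom.logpmf(support, N, n_a, n_b)
    p_co = float(np.exp(logsumexp(logpmf[support >= k])))
    p_ex = float(np.exp(logsumexp(logpmf[support <= k])))
    return min(p_co, 1.0), min(p_ex, 1.0)


def adjust_pvalues(pvalues, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, or pass-through for "none"."""
    p = np.asarray(list(pvalues), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method.lower() == "none":
        return p
    if method.upper() == "BH":
        if p.size == 0:
            return p
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def interaction_matrix(
    presence: pd.DataFrame, alpha: float = 0.05, adjust: str = "BH"
) -> list[InteractionResult]:
    """Test all unordered group pairs of a binary presence matrix.

    The candidate direction of each testable pair is its smaller tail; the
    candidate p-values of all testable pairs are adjusted together and the
    direction is kept only when q <= alpha.
    """
    X = presence.to_numpy(dtype=int)
    groups = list(presence.columns)
    N = X.shape[0]
    margins = X.sum(axis=0)
    testable: list[tuple[int, int, int, float, float, float]] = []
    untestable: list[tuple[int, int]] = []
    for i, j in combinations(range(len(groups)), 2):
        if margins[i] == 0 or margins[j] == 0:
            untestable.append((i, j))
            continue
        k = int(np.sum(X[:, i] & X[:, j]))
        p_co, p_ex = hypergeom_tails(N, int(margins[i]), int(margins[j]), k)
        testable.append((i, j, k, p_co, p_ex, min(p_co, p_ex)))
    qvals = adjust_pvalues([t[5] for t in testable], adjust)
    results = []
    for (i, j, k, p_co, p_ex, p_min), q in zip(testable, qvals):
        if q <= alpha:
            direction = "co-occurring" if p_co <= p_ex else "exclusive"
        else:
            direction = "none"
        results.append(
            InteractionResult(
                groups[i], groups[j], N, int(margins[i]), int(margins[j]),
                k, p_co, p_ex, float(q), direction,
            )
        )
    for i, j in untestable:
        results.append(
            InteractionResult(
                groups[i], groups[j], N, int(margins[i]), int(margins[j]),
                0, np.nan, np.nan, np.nan, "untestable",
            )
        )
    return results


def results_to_frame(results: list[InteractionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.group_a, r.group_b, r.N, r.n_a, r.n_b, r.k, r.p_co, r.p_ex, r.q, r.direction)
            for r in results
        ],
        columns=["group_a", "group_b", "N", "n_a", "n_b", "k", "p_co", "p_ex", "q", "direction"],
    )


def signed_log_q_matrix(results: list[InteractionResult]) -> pd.DataFrame:
    """Symmetric groups x groups matrix of signed -log10 q for rendering:
    positive = co-occurrence, negative = exclusivity, NaN = untestable or
    no call."""
    groups = sorted({r.group_a for r in results} | {r.group_b for r in results})
    M = pd.DataFrame(np.nan, index=groups, columns=groups)
    for r in results:
        if r.direction in ("untestable", "none"):
            continue
        mag = -np.log10(max(r.q, 1e-300))
        val = mag if r.direction == "co-occurring" else -mag
        M.at[r.group_a, r.group_b] = val
        M.at[r.group_b, r.group_a] = val
    return M


def permutation_oracle(
    presence: pd.DataFrame,
    pair: tuple[str, str],
    n_perm: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical tail probabilities of the observed overlap under uniform
    re-placement of group b's presences among the N samples.

    For N <= 12 the distribution is enumerated exhaustively (a combinatorial
    identity with the hypergeometric tails); otherwise ``n_perm`` seeded
    Monte-Carlo placements are drawn. Returns ``(p_co, p_ex)``.
    """
    a = presence[pair[0]].to_numpy(dtype=int)
    b = presence[pair[1]].to_numpy(dtype=int)
    N = a.size
    n_a, n_b = int(a.sum()), int(b.sum())
    if n_a == 0 or n_b == 0:
        raise UntestablePairError("zero presence margin: test undefined")
    k_obs = int(np.sum(a & b))
    if N <= 12:
        from itertools import combinations as _comb

        a_idx = set(np.where(a == 1)[0])
        total = co = ex = 0
        for placement in _comb(range(N), n_b):
            k = len(a_idx.intersection(placement))
            total += 1
            co += k >= k_obs
            ex += k <= k_obs
        return co / total, ex / total
    rng = np.random.default_rng(seed)
    a_mask = a.astype(bool)
    co = ex = 0
    for _ in range(n_perm):
        placement = rng.choice(N, size=n_b, replace=False)
        k = int(a_mask[placement].sum())
        co += k >= k_obs
        ex += k <= k_obs
    return co / n_perm, ex / n_perm
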