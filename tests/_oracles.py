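"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by enumeration or a textbook formula,
deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from autozykit.data_io import MISSING, UNKNOWN_PARENT


# --- Wright path counting ---------------------------------------------------


def _all_ancestor_paths(parents: dict, start: str):
    """Yield (ancestor, frozenset(path nodes), n_edges) for every ancestral
    path from ``start`` upward, including the trivial path to itself."""
    stack = [(start, frozenset([start]), 0)]
    while stack:
        node, nodes, n = stack.pop()
        yield node, nodes, n
        for p in parents.get(node, (UNKNOWN_PARENT, UNKNOWN_PARENT)):
            if p != UNKNOWN_PARENT:
                stack.append((p, nodes | {p}, n + 1))


def wright_inbreeding(parents: dict, x: str, _memo=None) -> float:
    """F_x by Wright's path counting: sum over common ancestors A and pairs
    of paths (sire->A, dam->A) sharing only A of (1/2)^(n+n'+1) (1+F_A)."""
    memo = {} if _memo is None else _memo
    if x in memo:
        return memo[x]
    s, d = parents.get(x, (UNKNOWN_PARENT, UNKNOWN_PARENT))
    if UNKNOWN_PARENT in (s, d):
        memo[x] = 0.0
        return 0.0
    total = 0.0
    paths_d = list(_all_ancestor_paths(parents, d))
    for anc, set1, n1 in _all_ancestor_paths(parents, s):
        for anc2, set2, n2 in paths_d:
            if anc == anc2 and set1 & set2 == {anc}:
                total += 0.5 ** (n1 + n2 + 1) * (
                    1.0 + wright_inbreeding(parents, anc, memo))
    memo[x] = total
    return total


def random_pedigree(rng, n: int) -> list[tuple[str, str, str]]:
    """Random acyclic pedigree records of size ``n`` (parents precede ids)."""
    ids = [f"I{i}" for i in range(n)]
    recs = []
    for i, x in enumerate(ids):
        if i < 2 or rng.random() < 0.3:
            recs.append((x, "0", "0"))
        else:
            s, d = rng.choice(i, size=2, replace=False)
            recs.append((x, ids[s], ids[d]))
    return recs


# --- HMM path-sum -----------------------------------------------------------


def hmm_path_sum(b: np.ndarray, trans: list[np.ndarray], pi: np.ndarray):
    """Likelihood and posteriors by exhaustive enumeration of state paths.

    ``b`` is (S, M) emissions, ``trans[t]`` the transition matrix into step t
    (t = 1..S-1), ``pi`` the initial distribution.
    """
    S, M = b.shape
    like = 0.0
    gamma = np.zeros((S, M))
    for path in itertools.product(range(M), repeat=S):
        p = pi[path[0]] * b[0, path[0]]
        for t in range(1, S):
            p *= trans[t - 1][path[t - 1], path[t]] * b[t, path[t]]
        like += p
        for t in range(S):
            gamma[t, path[t]] += p
    return like, gamma / like


def hmm_backward_loglik(b: np.ndarray, trans: list[np.ndarray],
                        pi: np.ndarray) -> float:
    """Log-likelihood via an (unscaled) backward recursion."""
    S, M = b.shape
    beta = np.ones(M)
    for t in range(S - 1, 0, -1):
        beta = trans[t - 1] @ (b[t] * beta)
    return float(np.log((pi * b[0] * beta).sum()))


# --- ROH enumeration --------------------------------------------------------


def brute_roh(d, pos, min_snps, min_length, max_gap, density):
    """All maximal qualifying homozygous runs.

    Works from first principles on the candidate boundaries: every
    heterozygous/missing site and every over-long gap ends a candidate run,
    so the candidates are exactly the index stretches between consecutive
    boundaries; each is then checked against all thresholds.
    """
    d = np.asarray(d)
    pos = np.asarray(pos)
    n = len(d)
    hom = (d == 0) | (d == 2)
    out = []
    i = 0
    while i < n:
        if not hom[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hom[j + 1] and pos[j + 1] - pos[j] < max_gap:
            j += 1
        length = pos[j] - pos[i]
        count = j - i + 1
        if (count >= min_snps and length > min_length
                and count >= length / density):
            out.append((int(pos[i]), int(pos[j]), count))
        i = j + 1
    return out
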