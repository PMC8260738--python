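"""Independent brute-force oracles for chain-model inference.

Everything here enumerates all S**T label sequences explicitly and never
touches the dynamic-programming code paths it is used to check.
"""

import itertools

import numpy as np
from scipy.special import logsumexp


def path_score(lam: np.ndarray, scores: np.ndarray, path) -> float:
    s = sum(scores[t, y] for t, y in enumerate(path))
    s += sum(lam[path[t - 1], path[t]] for t in range(1, len(path)))
    return float(s)


def enum_log_partition(lam: np.ndarray, scores: np.ndarray) -> float:
    T, S = scores.shape
    return float(
        logsumexp([path_score(lam, scores, p) for p in itertools.product(range(S), repeat=T)])
    )


def enum_marginals(lam: np.ndarray, scores: np.ndarray) -> np.ndarray:
    T, S = scores.shape
    logz = enum_log_partition(lam, scores)
    marg = np.zeros((T, S))
    for p in itertools.product(range(S), repeat=T):
        w = np.exp(path_score(lam, scores, p) - logz)
        for t, y in enumerate(p):
            marg[t, y] += w
    return marg


def enum_best_path(lam: np.ndarray, scores: np.ndarray) -> list[int]:
    T, S = scores.shape
    best, best_score = None, -np.inf
    for p in itertools.product(range(S), repeat=T):
        sc = path_score(lam, scores, p)
        if sc > best_score + 1e-12:
            best, best_score = p, sc
    return list(best)
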