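"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
exhaustive path enumeration for the HMM, explicit normal-equations algebra
for OLS, the textbook Welch formulas, and exhaustive label permutation for
small two-sample contrasts.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from cnvsmoke.cnvcall import HMMParams, emission_loglik


def brute_force_viterbi(panel, hmm: HMMParams, subject: int = 0) -> np.ndarray:
    """Best state path by scoring every one of the 4^P possible paths."""
    emis = emission_loglik(panel, hmm)[subject]       # P x 4
    n_probes = emis.shape[0]
    log_t = np.full((4, 4), np.log((1.0 - hmm.stay_prob) / 3.0))
    np.fill_diagonal(log_t, np.log(hmm.stay_prob))
    log_pi = np.full(4, (1.0 - hmm.stay_prob) / 3.0)
    log_pi[2] = hmm.stay_prob
    log_pi = np.log(log_pi)

    paths = np.array(np.unravel_index(np.arange(4 ** n_probes),
                                      (4,) * n_probes)).T  # (4^P, P)
    score = log_pi[paths[:, 0]] + emis[0, paths[:, 0]]
    for p in range(1, n_probes):
        score += log_t[paths[:, p - 1], paths[:, p]] + emis[p, paths[:, p]]
    return paths[int(np.argmax(score))]


def ols_normal_equations(y, X):
    """OLS by explicit normal equations: beta, se, t, p for each column."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, df


def welch_formulas(a, b):
    """Welch two-sample t and p from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = a.size, b.size
    t = (np.mean(a) - np.mean(b)) / np.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def exact_permutation_p(a, b) -> float:
    """Exact two-sided permutation p for the mean difference, all relabelings."""
    pooled = np.concatenate([a, b])
    na = len(a)
    obs = abs(np.mean(a) - np.mean(b))
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        diff = abs(pooled[mask].mean() - pooled[~mask].mean())
        count += diff >= obs - 1e-12
        total += 1
    return count / total
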