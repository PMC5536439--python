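"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np

from admixscan.ancestry import FREQ_FLOOR


def exhaustive_posterior(genotypes, positions, fa, fe, cfg):
    """Independent oracle: enumerate every pair of haplotype label paths.

    Works at the haplotype level (2^M x 2^M paths), a different
    factorization from the implementation's diploid copy-count chain.
    """
    m = len(positions)
    lam = cfg.lambda_eur
    fa = np.clip(np.asarray(fa, float), FREQ_FLOOR, 1 - FREQ_FLOOR)
    fe = np.clip(np.asarray(fe, float), FREQ_FLOOR, 1 - FREQ_FLOOR)
    c = 1 - np.exp(-cfg.generations * cfg.recomb_rate * np.diff(np.asarray(positions, float)))

    def path_prob(h):
        p = lam if h[0] == 1 else 1 - lam
        for j in range(1, m):
            stat = lam if h[j] == 1 else 1 - lam
            p *= (1 - c[j - 1]) * (h[j] == h[j - 1]) + c[j - 1] * stat
        return p

    def emit(g, h1, h2, j):
        if np.isnan(g):
            return 1.0
        p1 = fe[j] if h1 == 1 else fa[j]
        p2 = fe[j] if h2 == 1 else fa[j]
        probs = {
            0: (1 - p1) * (1 - p2),
            1: p1 * (1 - p2) + (1 - p1) * p2,
            2: p1 * p2,
        }
        return probs[int(g)]

    post = np.zeros((m, 3))
    total = 0.0
    for h1 in itertools.product((0, 1), repeat=m):
        for h2 in itertools.product((0, 1), repeat=m):
            w = path_prob(h1) * path_prob(h2)
            for j in range(m):
                w *= emit(genotypes[j], h1[j], h2[j], j)
            total += w
            for j in range(m):
                post[j, h1[j] + h2[j]] += w
    return post / total

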