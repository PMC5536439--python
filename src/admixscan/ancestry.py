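"""Local and global ancestry inference and principal components.

Local ancestry is inferred with a diploid hidden Markov model over
European-copy counts {0, 1, 2}: the two haplotypes evolve as independent
Markov chains that between adjacent markers are re-drawn from the
stationary ancestry distribution with probability 1 - exp(-G*r*d)
(exponential tract-length model for a single-pulse admixture G generations
ago at per-bp recombination rate r), and emissions are binomial mixtures
driven by ancestry-specific allele frequencies.  Decoding is by per-marker
posterior mode (forward-backward), matching the downstream use of calls as
an additive 0/1/2 dosage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import AdmixtureConfig, haplotype_switch_prob, validate_panel

# Panel frequencies are estimates; flooring keeps a single conflicting
# genotype from zeroing out an entire chain.
FREQ_FLOOR = 1e-4


@dataclass
class LocalAncestryMatrix:
    """Inferred European-copy counts with optional per-state posteriors.

    calls     : n x M int array in {0, 1, 2}
    posterior : n x M x 3 array, rows summing to 1; calls = argmax over axis 2
    marker_id : length-M marker labels aligned to the panel
    """

    calls: np.ndarray
    marker_id: np.ndarray
    posterior: Optional[np.ndarray] = None


def select_aims(panel: pd.DataFrame, delta_min: float = 0.2) -> pd.DataFrame:
    """Retain markers whose ancestral allele-frequency difference
    |freq_afr - freq_eur| strictly exceeds ``delta_min``."""
    validate_panel(panel)
    delta = (panel["freq_afr"] - panel["freq_eur"]).abs()
    out = panel.loc[delta > delta_min]
    if len(out) == 0:
        import warnings

        warnings.warn("no markers exceed the delta threshold; returning empty panel")
    return out


def ld_prune(
    genotypes: np.ndarray,
    r2_max: float = 0.1,
    window: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns a boolean keep-mask over markers.

    Within each window of ``window`` markers, for every pair with squared
    Pearson correlation > r2_max the later-position marker is dropped; the
    window then slides by ``step``.  Constant markers have undefined
    correlation, treated as 0 (never pruned for LD).
    """
    g = np.asarray(genotypes, float)
    n, m = g.shape
    if m < 2:
        raise ValueError("need at least 2 markers to prune")
    keep = np.ones(m, bool)
    # mean-impute missing entries for the correlation computation only
    col_mean = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    gi = np.where(np.isnan(g), col_mean[None, :], g)
    sd = gi.std(axis=0)
    start = 0
    while True:
        end = min(start + window, m)
        idx = [j for j in range(start, end) if keep[j]]
        for a_pos in range(len(idx)):
            a = idx[a_pos]
            if not keep[a]:
                continue
            for b in idx[a_pos + 1 :]:
                if not keep[b]:
                    continue
                if sd[a] == 0 or sd[b] == 0:
                    continue
                r = np.corrcoef(gi[:, a], gi[:, b])[0, 1]
                if r * r > r2_max:
                    keep[b] = False
        if end == m:
            break
        start += step
    return keep


def _diploid_transition(switch_p: float, lam: float) -> np.ndarray:
    """3x3 transition matrix over European-copy counts for one inter-marker
    gap, from two independent exchangeable haplotype chains."""
    # per-haplotype: EUR->EUR and AFR->EUR probabilities
    p_e_e = (1.0 - switch_p) + switch_p * lam
    p_a_e = switch_p * lam
    T = np.empty((3, 3))
    for k in range(3):  # current EUR copies
        # each of k EUR haplotypes stays EUR w.p. p_e_e; each of 2-k AFR
        # haplotypes becomes EUR w.p. p_a_e; next count = sum of Bernoullis
        probs = np.zeros(3)
        for e_stay in range(k + 1):
            from math import comb

            pe = comb(k, e_stay) * p_e_e**e_stay * (1 - p_e_e) ** (k - e_stay)
            for a_gain in range(2 - k + 1):
                pa = comb(2 - k, a_gain) * p_a_e**a_gain * (1 - p_a_e) ** (2 - k - a_gain)
                probs[e_stay + a_gain] += pe * pa
        T[k] = probs
    return T


def _emission_probs(fa: np.ndarray, fe: np.ndarray) -> np.ndarray:
    """Emission P(genotype g | k EUR copies) per marker; shape (M, 3, 3)
    indexed [marker, k, g].  Alt-allele probability is freq_eur on a EUR
    haplotype and freq_afr on an AFR haplotype; haplotypes within a state
    are exchangeable."""
    fa = np.clip(fa, FREQ_FLOOR, 1 - FREQ_FLOOR)
    fe = np.clip(fe, FREQ_FLOOR, 1 - FREQ_FLOOR)
    m = len(fa)
    out = np.empty((m, 3, 3))
    for k, (p1, p2) in enumerate([(fa, fa), (fa, fe), (fe, fe)]):
        out[:, k, 0] = (1 - p1) * (1 - p2)
        out[:, k, 1] = p1 * (1 - p2) + (1 - p1) * p2
        out[:, k, 2] = p1 * p2
    return out


def forward_backward(
    genotypes: np.ndarray,
    positions: np.ndarray,
    freq_afr: np.ndarray,
    freq_eur: np.ndarray,
    config: AdmixtureConfig,
) -> np.ndarray:
    """Posterior P(EUR copies = k) for every individual and marker on one
    chromosome.  ``genotypes`` is n x M (NaN = missing, emission 1 for all
    states).  Returns an n x M x 3 array with rows summing to 1."""
    g = np.asarray(genotypes, float)
    n, m = g.shape
    lam = config.lambda_eur
    pi = np.array([(1 - lam) ** 2, 2 * lam * (1 - lam), lam**2])
    emis = _emission_probs(np.asarray(freq_afr, float), np.asarray(freq_eur, float))

    # per-marker observation likelihood, n x M x 3
    like = np.ones((n, m, 3))
    obs = ~np.isnan(g)
    gi = np.where(obs, g, 0).astype(int)
    for j in range(m):
        rows = obs[:, j]
        like[rows, j, :] = emis[j, :, gi[rows, j]]

    switch = haplotype_switch_prob(np.diff(np.asarray(positions, float)), config)
    trans = [_diploid_transition(s, lam) for s in switch]

    alpha = np.empty((n, m, 3))
    scale = np.empty((n, m))
    a = pi[None, :] * like[:, 0, :]
    scale[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / scale[:, 0, None]
    for j in range(1, m):
        a = (alpha[:, j - 1, :] @ trans[j - 1]) * like[:, j, :]
        scale[:, j] = a.sum(axis=1)
        alpha[:, j, :] = a / scale[:, j, None]

    beta = np.empty((n, m, 3))
    beta[:, m - 1, :] = 1.0
    for j in range(m - 2, -1, -1):
        b = (beta[:, j + 1, :] * like[:, j + 1, :]) @ trans[j].T
        beta[:, j, :] = b / scale[:, j + 1, None]

    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post


def infer_local_ancestry(
    genotypes: np.ndarray,
    panel: pd.DataFrame,
    config: AdmixtureConfig,
    keep_posterior: bool = True,
) -> LocalAncestryMatrix:
    """Run the diploid HMM chromosome by chromosome and decode by posterior
    mode.  Markers are assumed AIM-selected and LD-pruned; genotype columns
    must align with the panel rows."""
    validate_panel(panel)
    g = np.asarray(genotypes, float)
    n, m = g.shape
    if m != len(panel):
        raise ValueError("genotype columns do not match panel")
    post = np.empty((n, m, 3))
    col = 0
    for _, sub in panel.groupby("chrom", sort=False):
        k = len(sub)
        post[:, col : col + k, :] = forward_backward(
            g[:, col : col + k],
            sub["pos"].to_numpy(),
            sub["freq_afr"].to_numpy(),
            sub["freq_eur"].to_numpy(),
            config,
        )
        col += k
    calls = post.argmax(axis=2).astype(np.int8)
    return LocalAncestryMatrix(
        calls=calls,
        marker_id=panel["marker_id"].to_numpy(),
        posterior=post if keep_posterior else None,
    )


def global_ancestry(la: LocalAncestryMatrix) -> np.ndarray:
    """Per-individual European ancestry proportion: sum of 0/1/2 calls over
    markers divided by twice the marker count (proportion scale)."""
    calls = np.asarray(la.calls)
    if calls.shape[1] == 0:
        raise ValueError("no markers")
    return calls.sum(axis=1) / (2.0 * calls.shape[1])


def compute_pcs(genotypes: np.ndarray, k: int = 10) -> np.ndarray:
    """Principal-component scores for stratification adjustment.

    Missing genotypes are mean-imputed per marker; columns are centered by
    2f and scaled by sqrt(2f(1-f)) (unit variance under binomial sampling);
    scores are left singular vectors scaled by singular values.  Sign fixed
    so the largest-magnitude loading of each component is positive.
    """
    g = np.asarray(genotypes, float)
    n, m = g.shape
    if n <= 1:
        raise ValueError("need at least 2 individuals")
    k_eff = min(k, n - 1, m)
    if k_eff < k:
        import warnings

        warnings.warn(f"only {k_eff} components available for n = {n}")
    col_mean = np.nanmean(g, axis=0)
    gi = np.where(np.isnan(g), col_mean[None, :], g)
    f = col_mean / 2.0
    denom = np.sqrt(2.0 * f * (1.0 - f))
    ok = denom > 0
    x = np.zeros_like(gi)
    x[:, ok] = (gi[:, ok] - 2.0 * f[None, ok]) / denom[None, ok]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for j in range(k_eff):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    return u[:, :k_eff] * s[None, :k_eff]
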