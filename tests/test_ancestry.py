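"""AIM selection, LD pruning, the local-ancestry HMM, global ancestry, PCA."""

import numpy as np
import pandas as pd
import pytest

from admixscan import ancestry
from oracles import exhaustive_posterior
from admixscan.ancestry import (
    LocalAncestryMatrix,
    compute_pcs,
    forward_backward,
    global_ancestry,
    infer_local_ancestry,
    ld_prune,
    select_aims,
)
from admixscan.simulate import AdmixtureConfig, PhenotypeConfig, make_aim_panel, simulate_cohort


def _panel(freqs, positions):
    fa, fe = zip(*freqs)
    return pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(len(fa))],
            "chrom": ["1"] * len(fa),
            "pos": positions,
            "ref": ["A"] * len(fa),
            "alt": ["G"] * len(fa),
            "freq_afr": fa,
            "freq_eur": fe,
        }
    )



class TestSelectAims:
    def test_boundary_and_retention(self):
        panel = _panel([(0.5, 0.5), (0.73, 0.17), (0.6, 0.4)], [100, 200, 300])
        kept = select_aims(panel, delta_min=0.2)
        assert list(kept["marker_id"]) == ["m1"]  # delta 0.56 retained

    def test_exact_threshold_excluded(self):
        panel = _panel([(0.6, 0.4)], [100])  # delta exactly 0.2
        assert len(select_aims(panel, delta_min=0.2)) == 0

    def test_empty_result_warns(self):
        panel = _panel([(0.5, 0.5)], [100])
        with pytest.warns(UserWarning):
            out = select_aims(panel)
        assert len(out) == 0


class TestLdPrune:
    def test_duplicate_column_pruned(self, rng):
        g = rng.integers(0, 3, size=(200, 5)).astype(float)
        g[:, 3] = g[:, 1]
        keep = ld_prune(g)
        assert keep[1] and not keep[3]  # earlier column kept

    def test_three_identical_columns_one_survivor(self, rng):
        g = rng.integers(0, 3, size=(200, 6)).astype(float)
        g[:, 2] = g[:, 0]
        g[:, 4] = g[:, 0]
        keep = ld_prune(g)
        assert keep[0] and not keep[2] and not keep[4]

    def test_independent_markers_mostly_retained(self, rng):
        g = rng.binomial(2, 0.4, size=(500, 200)).astype(float)
        keep = ld_prune(g)
        assert keep.mean() >= 0.95

    def test_constant_marker_not_pruned_for_ld(self, rng):
        g = rng.integers(0, 3, size=(100, 3)).astype(float)
        g[:, 1] = 1.0
        keep = ld_prune(g)
        assert keep[1]


class TestHmm:
    def test_fixed_difference_single_marker(self):
        panel = _panel([(0.0, 1.0)], [1000])
        cfg = AdmixtureConfig()
        la = infer_local_ancestry(np.array([[2.0]]), panel, cfg)
        assert la.calls[0, 0] == 2
        assert la.posterior[0, 0, 2] > 0.999

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_forward_backward_matches_exhaustive_paths(self, m, rng):
        cfg = AdmixtureConfig(seed=0)
        positions = np.cumsum(rng.integers(50_000, 3_000_000, m))
        fa = rng.uniform(0.05, 0.95, m)
        fe = rng.uniform(0.05, 0.95, m)
        g = rng.integers(0, 3, m).astype(float)
        g[0] = np.nan if m == 4 else g[0]  # exercise the missing path once
        post = forward_backward(g[None, :], positions, fa, fe, cfg)[0]
        oracle = exhaustive_posterior(g, positions, fa, fe, cfg)
        assert np.max(np.abs(post - oracle)) < 1e-10

    def test_posterior_rows_sum_to_one(self, small_cohort, admix_config):
        la = infer_local_ancestry(small_cohort.genotypes, small_cohort.panel, admix_config)
        sums = la.posterior.sum(axis=2)
        assert np.max(np.abs(sums - 1)) < 1e-8
        assert np.array_equal(la.calls, la.posterior.argmax(axis=2))

    def test_accuracy_against_truth(self, small_cohort, admix_config):
        la = infer_local_ancestry(small_cohort.genotypes, small_cohort.panel, admix_config)
        acc = np.mean(la.calls == small_cohort.true_local_ancestry)
        assert acc >= 0.90

    def test_accuracy_nondecreasing_in_delta(self):
        accs = []
        for delta in (0.3, 0.6, 0.9):
            freqs = [(0.5 + delta / 2, 0.5 - delta / 2)] * 120
            panel = _panel(freqs, np.arange(1, 121) * 140_000)
            acfg = AdmixtureConfig(seed=77)
            cohort = simulate_cohort(panel, acfg, PhenotypeConfig(n_individuals=150, seed=88))
            la = infer_local_ancestry(cohort.genotypes, cohort.panel, acfg, keep_posterior=False)
            accs.append(np.mean(la.calls == cohort.true_local_ancestry))
        assert accs[0] <= accs[1] + 0.01 <= accs[2] + 0.02

    def test_accuracy_nondecreasing_in_density(self):
        accs = []
        for spacing in (1_000_000, 140_000):
            panel = make_aim_panel(150, seed=5, n_chrom=2, spacing_bp=spacing)
            acfg = AdmixtureConfig(seed=6)
            cohort = simulate_cohort(panel, acfg, PhenotypeConfig(n_individuals=150, seed=7))
            la = infer_local_ancestry(cohort.genotypes, cohort.panel, acfg, keep_posterior=False)
            accs.append(np.mean(la.calls == cohort.true_local_ancestry))
        assert accs[0] <= accs[1] + 0.01

    def test_extreme_frequencies_do_not_lock(self):
        # genotype impossible under unfloored frequencies must not crash
        panel = _panel([(0.0, 1.0), (0.0, 1.0)], [1000, 2000])
        cfg = AdmixtureConfig()
        la = infer_local_ancestry(np.array([[2.0, 0.0]]), panel, cfg)
        assert np.all(np.isfinite(la.posterior))


class TestGlobalAncestry:
    def test_hand_sum(self):
        la = LocalAncestryMatrix(
            calls=np.array([[2, 1, 0, 1]]), marker_id=np.array(list("abcd"))
        )
        assert global_ancestry(la)[0] == pytest.approx(0.5)

    def test_extremes(self):
        la = LocalAncestryMatrix(calls=np.full((2, 5), 2), marker_id=np.arange(5))
        assert np.all(global_ancestry(la) == 1.0)
        la = LocalAncestryMatrix(calls=np.zeros((2, 5), int), marker_id=np.arange(5))
        assert np.all(global_ancestry(la) == 0.0)

    def test_no_markers_rejected(self):
        la = LocalAncestryMatrix(calls=np.empty((2, 0), int), marker_id=np.array([]))
        with pytest.raises(ValueError):
            global_ancestry(la)

    def test_mean_theta_near_lambda(self, small_cohort, admix_config):
        la = infer_local_ancestry(
            small_cohort.genotypes, small_cohort.panel, admix_config, keep_posterior=False
        )
        theta = global_ancestry(la)
        se = theta.std() / np.sqrt(len(theta))
        assert abs(theta.mean() - 0.2) < 4 * se + 0.02


class TestPcs:
    def test_scores_orthogonal(self, small_cohort):
        pcs = compute_pcs(small_cohort.genotypes, k=5)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(gram))

    def test_two_population_toy_separates(self, rng):
        # 20 EUR-like vs 20 AFR-like individuals at 50 high-delta markers
        f_eur, f_afr = 0.9, 0.1
        g = np.vstack(
            [
                rng.binomial(2, f_eur, size=(20, 50)),
                rng.binomial(2, f_afr, size=(20, 50)),
            ]
        ).astype(float)
        pc1 = compute_pcs(g, k=2)[:, 0]
        assert max(pc1[20:]) < min(pc1[:20]) or max(pc1[:20]) < min(pc1[20:])

    def test_sign_convention_deterministic(self, small_cohort):
        a = compute_pcs(small_cohort.genotypes, k=3)
        b = compute_pcs(small_cohort.genotypes, k=3)
        assert np.array_equal(a, b)

    def test_small_n_returns_fewer_components(self, rng):
        g = rng.binomial(2, 0.5, size=(4, 30)).astype(float)
        with pytest.warns(UserWarning):
            pcs = compute_pcs(g, k=10)
        assert pcs.shape == (4, 3)
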