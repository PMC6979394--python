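"""Founder-tracing HMM: filters, forward-backward oracle, calls, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mpqtl import synthetic_population as sp
from mpqtl.ibd_hmm import HmmParams, filter_snps_for_ibd, fit_mosaic, tracing_power
from mpqtl.io_formats import MISSING, UNKNOWN, GeneticMap, GenotypeMatrix, MosaicPath


def brute_force_posteriors(obs, founder_alleles, dist_morgan, params):
    """Path-enumeration oracle for one line: sum over all F**S hidden paths.

    Independent of the forward-backward code: builds the joint probability
    of every path explicitly and marginalizes.
    """
    F, S = founder_alleles.shape
    eps = params.epsilon
    stay = np.exp(-params.G * np.asarray(dist_morgan))
    switch = 1 - stay

    def emit(s, f):
        o = obs[s]
        if o < 0:
            return 1.0
        return 1.0 - eps if founder_alleles[f, s] == o else eps

    def trans(s, f_from, f_to):
        if params.redraw == "any":
            p = switch[s] / F
            return stay[s] + p if f_from == f_to else p
        return stay[s] if f_from == f_to else switch[s] / (F - 1)

    post = np.zeros((S, F))
    total = 0.0
    from itertools import product

    for path in product(range(F), repeat=S):
        p = emit(0, path[0]) / F
        for s in range(1, S):
            p *= trans(s - 1, path[s - 1], path[s]) * emit(s, path[s])
        total += p
        for s in range(S):
            post[s, path[s]] += p
    return post / total


def _matrix_from_dosage(dosage, positions=None, chrom="1"):
    dosage = np.asarray(dosage, dtype=np.int8)
    S = dosage.shape[1]
    pos = positions if positions is not None else (np.arange(S) + 1) * 1000
    markers = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "T"})
    return GenotypeMatrix(
        samples=[f"L{i}" for i in range(dosage.shape[0])],
        markers=markers, dosage=dosage)


class TestFilter:
    def test_het_and_missing_rules(self):
        """Hand-built 10-marker matrix: 3 markers violating a rule, 7 kept."""
        n = 20
        d = np.zeros((n, 10), dtype=np.int8)
        d[:3, 1] = 1        # 15% heterozygous -> removed
        d[:6, 4] = MISSING  # 30% missing -> removed
        d[:3, 7] = 1        # 15% heterozygous -> removed
        d[:2, 9] = 1        # 10% heterozygous -> at threshold, kept
        kept = filter_snps_for_ibd(_matrix_from_dosage(d))
        assert kept.n_markers == 7
        kept_pos = set(kept.markers["pos"])
        all_pos = set(_matrix_from_dosage(d).markers["pos"])
        removed = sorted(all_pos - kept_pos)
        assert removed == [2000, 5000, 8000]

    def test_clean_marker_retained(self):
        d = np.tile([0, 2], (10, 3))[:, :3].astype(np.int8)
        kept = filter_snps_for_ibd(_matrix_from_dosage(d))
        assert kept.n_markers == 3

    def test_empty_result_warns(self):
        d = np.ones((4, 2), dtype=np.int8)  # all heterozygous
        with pytest.warns(UserWarning):
            kept = filter_snps_for_ibd(_matrix_from_dosage(d))
        assert kept.n_markers == 0


class TestForwardBackward:
    def test_unambiguous_copy_single_segment(self):
        """Progeny identical to founder 1 of 2 fully divergent founders."""
        S = 30
        founders = sp.FounderPanel(
            founders=["A", "B"],
            alleles=np.vstack([np.zeros(S), np.ones(S)]).astype(np.int8),
            markers=pd.DataFrame({"chrom": "1", "pos": (np.arange(S) + 1) * 1000,
                                  "ref": "A", "alt": "T"}))
        gmap = GeneticMap(pd.DataFrame({
            "chrom": "1", "pos_bp": [1000, S * 1000], "cM": [0.0, 10.0]}))
        progeny = _matrix_from_dosage(np.zeros((1, S)))
        post, mosaic = fit_mosaic(progeny, founders, gmap,
                                  HmmParams(G=9, epsilon=0.0))
        assert (post["1"][0, :, 0] > 0.999).all()
        assert len(mosaic.segments["L0"]["1"]) == 1
        assert mosaic.segments["L0"]["1"][0, 2] == 0

    def test_matches_enumeration_small_case(self):
        """3 markers, 2 founders, epsilon=0.1, d=0.1 M: exact agreement."""
        fa = np.array([[0, 1, 0], [1, 0, 1]], dtype=np.int8)
        obs = np.array([0, 0, 1], dtype=np.int8)
        params = HmmParams(G=1.0, epsilon=0.1)
        oracle = brute_force_posteriors(obs, fa, [0.1, 0.1], params)

        founders = sp.FounderPanel(
            founders=["A", "B"], alleles=fa,
            markers=pd.DataFrame({"chrom": "1", "pos": [1000, 2000, 3000],
                                  "ref": "A", "alt": "T"}))
        gmap = GeneticMap(pd.DataFrame({
            "chrom": "1", "pos_bp": [1000, 2000, 3000], "cM": [0.0, 10.0, 20.0]}))
        progeny = _matrix_from_dosage((2 * obs)[None, :])
        post, _ = fit_mosaic(progeny, founders, gmap, params)
        np.testing.assert_allclose(post["1"][0], oracle, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        S=st.integers(2, 6),
        F=st.integers(2, 4),
        eps=st.sampled_from([0.0, 0.05, 0.2]),
        redraw=st.sampled_from(["any", "distinct"]),
        data=st.data(),
    )
    def test_posterior_equals_path_enumeration(self, S, F, eps, redraw, data):
        """Forward-backward equals brute-force path summation to 1e-12."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        fa = rng.integers(0, 2, size=(F, S)).astype(np.int8)
        # observations drawn from alleles carried by some founder (or missing)
        # so that the epsilon = 0 case stays well defined
        obs = np.array([
            -9 if rng.random() < 0.2 else fa[rng.integers(F), s]
            for s in range(S)
        ], dtype=np.int8)
        dist = rng.uniform(0.0, 0.3, size=S - 1)
        params = HmmParams(G=rng.uniform(0.5, 10), epsilon=eps, redraw=redraw)
        oracle = brute_force_posteriors(obs, fa, dist, params)

        from mpqtl.ibd_hmm import _forward_backward

        post = _forward_backward(obs[None, :], fa, dist, params)[0]
        np.testing.assert_allclose(post, oracle, atol=1e-12)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_distance_is_identity_transition(self):
        """d -> 0: both markers share one posterior (no switching mass)."""
        fa = np.array([[0, 0], [1, 1]], dtype=np.int8)
        obs = np.array([[0, -9]], dtype=np.int8)
        from mpqtl.ibd_hmm import _forward_backward

        post = _forward_backward(obs, fa, np.array([0.0]), HmmParams(epsilon=0.1))
        np.testing.assert_allclose(post[0, 0], post[0, 1], atol=1e-12)


class TestCallsAndPower:
    def test_tracing_power_hand_case(self):
        """10 markers, 3 mismatches -> 0.7."""
        pos = (np.arange(10) + 1) * 100
        markers = pd.DataFrame({"chrom": "1", "pos": pos})
        truth = MosaicPath(segments={"L1": {"1": np.array([[1, 1000, 0]])}},
                           extents={"1": (1, 1000)})
        inferred = MosaicPath(
            segments={"L1": {"1": np.array([[1, 250, 1], [251, 950, 0],
                                            [951, 1000, UNKNOWN]])}},
            extents={"1": (1, 1000)})
        # markers 100,200 under founder 1 (wrong); 1000 under UNKNOWN (wrong)
        assert tracing_power(truth, inferred, markers) == pytest.approx(0.7)

    def test_perfect_and_unknown_extremes(self, pseudo_pop):
        truth, geno = pseudo_pop
        assert tracing_power(truth, truth, geno.markers) == 1.0
        all_unknown = MosaicPath(
            segments={ln: {c: np.array([[truth.extents[c][0], truth.extents[c][1],
                                         UNKNOWN]])
                           for c in truth.chromosomes}
                      for ln in truth.lines},
            extents=dict(truth.extents))
        assert tracing_power(truth, all_unknown, geno.markers) == 0.0

    def test_pseudoprogeny_recovery(self, founders8, small_map, pseudo_pop):
        """Informative founders: genome-wide correct-call fraction >= 0.93."""
        truth, geno = pseudo_pop
        _, inferred = fit_mosaic(geno, founders8, small_map, HmmParams(G=9))
        assert tracing_power(truth, inferred, geno.markers) >= 0.93

    def test_epsilon_monotonicity(self, founders8, small_map):
        """Raising epsilon never raises mean tracing power (5 seeds)."""
        grid = [0.0, 0.05, 0.15, 0.3]
        means = []
        for eps in grid:
            powers = []
            for seed in range(5):
                truth, geno = sp.simulate_pseudoprogeny(
                    founders8, small_map, n_lines=8, n_segments=10, seed=seed)
                # corrupt a fraction eps of calls to match the emission model
                rng = np.random.default_rng(seed + 1000)
                d = geno.dosage.copy()
                flip = rng.random(d.shape) < eps
                d[flip] = 2 - d[flip]
                noisy = GenotypeMatrix(geno.samples, geno.markers, d)
                _, inf = fit_mosaic(noisy, founders8, small_map,
                                    HmmParams(G=9, epsilon=max(eps, 0.01)))
                powers.append(tracing_power(truth, inf, geno.markers))
            means.append(np.mean(powers))
        assert all(means[i] + 1e-9 >= means[i + 1] for i in range(len(means) - 1))

    def test_marker_mismatch_rejected(self, founders8, small_map, pseudo_pop):
        _, geno = pseudo_pop
        shifted = geno.markers.copy()
        shifted["pos"] = shifted["pos"] + 1
        bad = GenotypeMatrix(geno.samples, shifted, geno.dosage)
        with pytest.raises(ValueError, match="missing from the founder panel"):
            fit_mosaic(bad, founders8, small_map)
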