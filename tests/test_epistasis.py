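"""Pairwise interaction scan: pruning, two-stage filtering, variance, categories."""

import numpy as np
import pandas as pd
import pytest

from mpqtl.binning import BinMap
from mpqtl.epistasis import (
    EpiPair,
    adjust_pairs,
    categorize_pairs,
    joint_epistatic_variance,
    pairwise_scan,
    prune_variants,
    recombinant_fraction,
)
from mpqtl.io_formats import GenotypeMatrix, UNKNOWN
from mpqtl.sgwas import SQtl


def _geno(dosage, positions=None, chrom="1"):
    dosage = np.asarray(dosage, dtype=np.int8)
    S = dosage.shape[1]
    pos = positions if positions is not None else (np.arange(S) + 1) * 1000
    return GenotypeMatrix(
        samples=[f"L{i}" for i in range(dosage.shape[0])],
        markers=pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "T"}),
        dosage=dosage)


def brute_force_prune(d, pos, r2_max):
    """Oracle: single-window greedy pruning by pairwise r2, in marker order."""
    keep = list(range(d.shape[1]))
    i = 0
    while i < len(keep):
        j = i + 1
        while j < len(keep):
            a, b = d[:, keep[i]].astype(float), d[:, keep[j]].astype(float)
            r2 = np.corrcoef(a, b)[0, 1] ** 2 if a.std() and b.std() else 0.0
            if r2 >= r2_max:
                del keep[j]
            else:
                j += 1
        i += 1
    return keep


class TestPrune:
    def test_duplicate_marker_removed(self, rng):
        x = rng.integers(0, 3, 50)
        geno = _geno(np.column_stack([x, x]), positions=[1000, 2000])
        pruned = prune_variants(geno, maf_min=0.0)
        assert pruned.n_markers == 1
        assert pruned.markers["pos"].tolist() == [1000]

    def test_independent_markers_retained(self, rng):
        d = rng.integers(0, 3, (300, 10))
        geno = _geno(d)
        assert prune_variants(geno, maf_min=0.0).n_markers == 10

    def test_matches_brute_force_within_window(self, rng):
        """10 markers inside one 50-kb window: greedy oracle agreement."""
        base = rng.integers(0, 3, (200, 4))
        cols = [base[:, i % 4] if i % 3 else base[:, 0] for i in range(10)]
        d = np.column_stack(cols).astype(np.int8)
        noise = rng.integers(0, 3, (200, 10))
        mix = np.where(rng.random((200, 10)) < 0.2, noise, d).astype(np.int8)
        pos = np.arange(10) * 4000 + 1000  # all within 50 kb
        geno = _geno(mix, positions=pos)
        pruned = prune_variants(geno, maf_min=0.0, step_snps=1)
        expected = brute_force_prune(mix, pos, 0.5)
        assert pruned.markers["pos"].tolist() == [pos[i] for i in expected]

    def test_maf_filter_applied_first(self, rng):
        d = rng.integers(0, 3, (100, 3)).astype(np.int8)
        d[:, 1] = 0
        d[0, 1] = 2  # MAF 1%
        geno = _geno(d)
        pruned = prune_variants(geno, maf_min=0.02)
        assert pruned.n_markers == 2


class TestPairwiseScan:
    def test_pure_interaction_retained(self, rng):
        n = 400
        ga = rng.integers(0, 3, n).astype(float)
        gb = rng.integers(0, 3, n).astype(float)
        d = np.column_stack([ga, gb, rng.integers(0, 3, n)]).astype(np.int8)
        geno = _geno(d, positions=[1000, 500_000, 900_000])
        y = (ga - ga.mean()) * (gb - gb.mean())
        pairs = pairwise_scan(geno, y, first_pass_p=1e-10)
        assert any(p.pos_a == 1000 and p.pos_b == 500_000 for p in pairs)

    def test_symmetry_in_marker_order(self, rng):
        n = 300
        ga = rng.integers(0, 3, n).astype(float)
        gb = rng.integers(0, 3, n).astype(float)
        y = (ga - ga.mean()) * (gb - gb.mean()) + 0.2 * rng.normal(size=n)
        g1 = _geno(np.column_stack([ga, gb]).astype(np.int8),
                   positions=[1000, 900_000])
        g2 = _geno(np.column_stack([gb, ga]).astype(np.int8),
                   positions=[1000, 900_000])
        p1 = pairwise_scan(g1, y, first_pass_p=1e-6)
        p2 = pairwise_scan(g2, y, first_pass_p=1e-6)
        assert p1[0].raw_p == pytest.approx(p2[0].raw_p, rel=1e-12)

    def test_null_interaction_calibrated(self):
        """Additive-only traits: interaction type-I error at 0.01 in band.

        10,000 null pairs accumulated over independent marker draws.
        """
        rng = np.random.default_rng(123)
        n = 250
        hits = 0
        total = 0
        from mpqtl.epistasis import _interaction_test

        for _ in range(10_000):
            ga = rng.integers(0, 3, n).astype(float)
            gb = rng.integers(0, 3, n).astype(float)
            y = ga + gb + rng.normal(size=n)
            p = _interaction_test(y, np.column_stack((ga, gb, ga * gb)))
            hits += p <= 0.01
            total += 1
        assert 0.005 <= hits / total <= 0.02

    def test_dedup_keeps_most_significant(self):
        pairs = [
            EpiPair("1", 100_000, 0, "2", 500_000, 1, 1e-20),
            EpiPair("1", 150_000, 2, "2", 520_000, 3, 1e-18),
            EpiPair("1", 120_000, 4, "2", 580_000, 5, 1e-17),
        ]
        from mpqtl.epistasis import _dedup_pairs

        kept = _dedup_pairs(pairs, window_bp=100_000)
        assert len(kept) == 1
        assert kept[0].raw_p == 1e-20

    def test_monomorphic_skipped(self, rng):
        d = np.zeros((100, 2), dtype=np.int8)
        d[:, 1] = rng.integers(0, 3, 100)
        geno = _geno(d)
        assert pairwise_scan(geno, rng.normal(size=100), first_pass_p=0.5) == []


class TestAdjustAndJointVariance:
    def test_confounded_pair_dropped_after_adjustment(self):
        """A raw hit driven by a structure axis loses significance with PCs."""
        rng = np.random.default_rng(7)
        n = 400
        group = np.repeat([0, 1], n // 2)
        ga = (group * 2 + rng.integers(0, 2, n)).clip(0, 2).astype(float)
        gb = (group * 2 + rng.integers(0, 2, n)).clip(0, 2).astype(float)
        y = 3.0 * (ga - ga.mean()) * (gb - gb.mean()) * 0 + 4.0 * group + \
            0.3 * rng.normal(size=n)
        geno = _geno(np.column_stack([ga, gb]).astype(np.int8),
                     positions=[1000, 900_000])
        pairs = [EpiPair("1", 1000, 0, "1", 900_000, 1, raw_p=1e-20)]
        pcs = (group - group.mean()).astype(float)[:, None]
        kept = adjust_pairs(pairs, geno, y, pcs, final_p=1e-12)
        assert kept == []

    def test_noise_free_interaction_pve(self, rng):
        n = 500
        ga = rng.integers(0, 3, n).astype(float)
        gb = rng.integers(0, 3, n).astype(float)
        y = (ga - ga.mean()) * (gb - gb.mean())
        geno = _geno(np.column_stack([ga, gb]).astype(np.int8),
                     positions=[1000, 900_000])
        pairs = [EpiPair("1", 1000, 0, "1", 900_000, 1, raw_p=0.0)]
        kept = adjust_pairs(pairs, geno, y, None, final_p=1e-6)
        assert len(kept) == 1
        assert kept[0].pve == pytest.approx(1.0, abs=0.05)
        joint = joint_epistatic_variance(kept, geno, y)
        assert joint >= kept[0].pve - 1e-9

    def test_duplicated_pair_deterministic(self, rng):
        n = 300
        ga = rng.integers(0, 3, n).astype(float)
        gb = rng.integers(0, 3, n).astype(float)
        y = (ga - ga.mean()) * (gb - gb.mean()) + 0.5 * rng.normal(size=n)
        geno = _geno(np.column_stack([ga, gb]).astype(np.int8),
                     positions=[1000, 900_000])
        pairs = [EpiPair("1", 1000, 0, "1", 900_000, 1, 1e-20),
                 EpiPair("1", 1000, 0, "1", 900_000, 1, 1e-20)]
        kept = adjust_pairs(pairs, geno, y, None, final_p=1.0)
        assert kept[0].adj_p == kept[1].adj_p

    def test_known_share_recovery(self):
        """One pair built to explain 10% of variance at n=1404: +/- 3 points."""
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 1404
            ga = rng.integers(0, 3, n).astype(float)
            gb = rng.integers(0, 3, n).astype(float)
            w = (ga - ga.mean()) * (gb - gb.mean())
            w = (w - w.mean()) / w.std()
            y = np.sqrt(0.10) * w + np.sqrt(0.90) * rng.normal(size=n)
            geno = _geno(np.column_stack([ga, gb]).astype(np.int8),
                         positions=[1000, 900_000])
            pairs = [EpiPair("1", 1000, 0, "1", 900_000, 1, 0.0)]
            ests.append(joint_epistatic_variance(pairs, geno, y))
        assert abs(np.mean(ests) - 0.10) < 0.03

    def test_no_pairs_gives_zero(self, pseudo_pop, rng):
        _, geno = pseudo_pop
        assert joint_epistatic_variance([], geno, rng.normal(size=geno.n_samples)) == 0.0


class TestCategorize:
    def _sqtl(self, trait, chrom, lo, hi):
        return SQtl(trait=trait, chrom=chrom, start_bp=lo, end_bp=hi,
                    peak_pos=(lo + hi) // 2, peak_p=1e-12, members=[lo, hi])

    def test_all_four_categories(self):
        catalog = [
            self._sqtl("t1", "1", 100_000, 200_000),
            self._sqtl("t1", "2", 100_000, 200_000),
            self._sqtl("t2", "3", 100_000, 200_000),
        ]
        pairs = [
            EpiPair("1", 150_000, 0, "2", 150_000, 1, 1e-20),  # SS-1 (same trait)
            EpiPair("1", 150_000, 0, "3", 150_000, 1, 1e-20),  # SS-2
            EpiPair("1", 150_000, 0, "9", 150_000, 1, 1e-20),  # SN
            EpiPair("8", 150_000, 0, "9", 150_000, 1, 1e-20),  # NN
        ]
        _, fractions = categorize_pairs(pairs, catalog, link_bp=50_000)
        assert fractions == {"SS-1": 0.25, "SS-2": 0.25, "SN": 0.25, "NN": 0.25}

    def test_linkage_window(self):
        catalog = [self._sqtl("t", "1", 100_000, 200_000)]
        near = EpiPair("1", 240_000, 0, "9", 1000, 1, 1e-20)   # within 50 kb
        far = EpiPair("1", 260_000, 0, "9", 1000, 1, 1e-20)    # beyond
        _, fr = categorize_pairs([near, far], catalog, link_bp=50_000)
        assert near.category == "SN" and far.category == "NN"


def test_recombinant_fraction():
    states = np.array([
        [0, 0], [0, 1], [1, 1], [UNKNOWN, 0], [2, 2],
    ])
    bm = BinMap(bins=pd.DataFrame({"chrom": "1", "start_bp": [1, 11],
                                   "end_bp": [10, 20]}),
                states=states, lines=list("abcde"))
    # among complete lines a,b,c,e: only b differs
    assert recombinant_fraction(bm, 0, 1) == pytest.approx(0.25)
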