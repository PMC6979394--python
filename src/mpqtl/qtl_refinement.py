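"""Phenotype-driven QTL refinement by a linkage-like analysis.

Major QTL (detected by both association scans with enough variance
explained) are refined in three steps. First the founder IBD groups at the
peak bin are collapsed into *functional alleles*: clusters of founders whose
progeny phenotypes are statistically indistinguishable, found by
agglomerative merging of founder groups until all between-cluster
comparisons are significant. Second the functional-allele labels are
projected onto every bin in the QTL region and the lines are re-clustered
into major haplotypes over the region. Third, pairwise phenotype tests
between major haplotypes classify each bin: a bin supports the QTL when
phenotypically distinct haplotype pairs disagree in allele there while
phenotypically equivalent pairs agree; the refined interval is the longest
run of supporting bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mpqtl.binning import BinMap
from mpqtl.hgwas import HQtl
from mpqtl.io_formats import UNKNOWN
from mpqtl.sgwas import SQtl

__all__ = [
    "FunctionalAlleleAssignment",
    "RefinementResult",
    "define_major_qtl",
    "collapse_functional_alleles",
    "narrow_interval",
]


@dataclass
class FunctionalAlleleAssignment:
    """Mapping from founder IBD states to phenotype-driven allele clusters."""

    peak_bin: int
    clusters: list[list[int]]  # founder states per cluster
    cluster_of: dict[int, int]  # founder state -> cluster index
    line_allele: np.ndarray  # per-line cluster label (UNKNOWN if unassigned)

    @property
    def n_alleles(self) -> int:
        return len(self.clusters)


@dataclass
class RefinementResult:
    chrom: str
    region: tuple[int, int]
    refined: tuple[int, int]
    informative: bool
    decisions: pd.DataFrame = field(default_factory=pd.DataFrame)
    haplotype_sizes: dict = field(default_factory=dict)


def define_major_qtl(
    sqtl: SQtl, hqtl: HQtl, pve_min: float = 0.10
) -> tuple[str, int, int] | None:
    """Region of a major QTL: the union of overlapping sQTL and hQTL intervals.

    Eligibility requires both loci on the same chromosome with physically
    overlapping intervals and both PVEs computed and >= ``pve_min``;
    otherwise None is returned.
    """
    if sqtl.chrom != hqtl.chrom:
        return None
    if sqtl.pve is None or hqtl.pve is None:
        return None
    if sqtl.pve < pve_min or hqtl.pve < pve_min:
        return None
    if sqtl.end_bp < hqtl.start_bp or hqtl.end_bp < sqtl.start_bp:
        return None
    return (sqtl.chrom, min(sqtl.start_bp, hqtl.start_bp),
            max(sqtl.end_bp, hqtl.end_bp))


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or len(b) < 2:
        return 1.0
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def collapse_functional_alleles(
    peak_states: np.ndarray,
    phenotype,
    p_collapse: float = 0.05,
    min_group_n: int = 2,
) -> FunctionalAlleleAssignment:
    """Collapse founder IBD groups into phenotypically distinguishable clusters.

    All pairwise unequal-variance t-tests are computed between founder-state
    groups at the peak bin; the pair of clusters with the largest P-value is
    merged repeatedly until every between-cluster comparison has
    P < ``p_collapse`` (or a single cluster remains, signalling no allelic
    series). Founder states carried by fewer than ``min_group_n`` lines are
    left unassigned.
    """
    y = np.asarray(phenotype, dtype=float)
    states = np.asarray(peak_states)
    groups: dict[int, np.ndarray] = {}
    for s in np.unique(states[states != UNKNOWN]):
        vals = y[states == s]
        if len(vals) >= min_group_n:
            groups[int(s)] = vals
    if len(groups) < 2:
        clusters = [sorted(groups)] if groups else []
    else:
        # all pairwise tests once, between the original founder groups; the
        # between-cluster p-value is the largest cross-pair p (single
        # linkage), which avoids the selection bias of re-testing pooled
        # clusters against each other
        keys = sorted(groups)
        pmat = {}
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                pmat[(a, b)] = _welch_p(groups[a], groups[b])

        def cross_p(ci, cj):
            return max(pmat[(min(a, b), max(a, b))] for a in ci for b in cj)

        clusters = [[s] for s in keys]
        while len(clusters) > 1:
            best_p, best_pair = -1.0, None
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    pv = cross_p(clusters[i], clusters[j])
                    if pv > best_p:
                        best_p, best_pair = pv, (i, j)
            if best_p < p_collapse:
                break
            i, j = best_pair
            clusters[i] = sorted(clusters[i] + clusters[j])
            del clusters[j]
    cluster_of = {s: k for k, members in enumerate(clusters) for s in members}
    line_allele = np.asarray(
        [cluster_of.get(int(s), UNKNOWN) if s != UNKNOWN else UNKNOWN for s in states],
        dtype=np.int64,
    )
    return FunctionalAlleleAssignment(
        peak_bin=-1, clusters=[list(c) for c in clusters],
        cluster_of=cluster_of, line_allele=line_allele,
    )


def narrow_interval(
    bins: BinMap,
    region_bin_idx: np.ndarray,
    assignment: FunctionalAlleleAssignment,
    phenotype,
    p_narrow: float = 0.01,
    min_hap_n: int = 9,
) -> RefinementResult:
    """Narrow a QTL region using recombinant major haplotypes.

    Functional-allele labels are projected onto every bin of the region,
    lines are grouped into major haplotypes (identical allele vectors,
    group size >= ``min_hap_n``), and each bin is scored: it supports the
    QTL when every phenotypically distinct haplotype pair (Welch t,
    P < ``p_narrow``) carries different alleles there and every equivalent
    pair carries the same allele. The refined interval is the longest run
    of supporting bins; with fewer than two major haplotypes, or no
    distinct pair, the region is returned unchanged and flagged.
    """
    y = np.asarray(phenotype, dtype=float)
    region_bin_idx = np.asarray(region_bin_idx, dtype=int)
    sub = bins.bins.iloc[region_bin_idx]
    chrom = str(sub["chrom"].iloc[0])
    region = (int(sub["start_bp"].min()), int(sub["end_bp"].max()))

    # project functional alleles onto every region bin
    A = np.full((len(bins.lines), len(region_bin_idx)), UNKNOWN, dtype=np.int64)
    for k, b in enumerate(region_bin_idx):
        col = bins.states[:, b]
        for i, s in enumerate(col):
            if s != UNKNOWN:
                A[i, k] = assignment.cluster_of.get(int(s), UNKNOWN)

    complete = ~np.any(A == UNKNOWN, axis=1)
    haps: dict[tuple, np.ndarray] = {}
    for i in np.flatnonzero(complete):
        haps.setdefault(tuple(A[i]), []).append(i)
    major = {h: np.asarray(idx) for h, idx in haps.items() if len(idx) >= min_hap_n}
    sizes = {h: len(idx) for h, idx in major.items()}
    if len(major) < 2:
        return RefinementResult(chrom, region, region, informative=False,
                                haplotype_sizes=sizes)

    hlist = list(major)
    distinct, equivalent = [], []
    for i in range(len(hlist)):
        for j in range(i + 1, len(hlist)):
            pv = _welch_p(y[major[hlist[i]]], y[major[hlist[j]]])
            (distinct if pv < p_narrow else equivalent).append((i, j))
    if not distinct:
        return RefinementResult(chrom, region, region, informative=False,
                                haplotype_sizes=sizes)

    support = np.zeros(len(region_bin_idx), dtype=bool)
    for k in range(len(region_bin_idx)):
        ok = all(hlist[i][k] != hlist[j][k] for i, j in distinct) and \
             all(hlist[i][k] == hlist[j][k] for i, j in equivalent)
        support[k] = ok

    decisions = pd.DataFrame({
        "chrom": chrom,
        "start_bp": sub["start_bp"].to_numpy(),
        "end_bp": sub["end_bp"].to_numpy(),
        "supports_qtl": support,
    })
    if not support.any():
        return RefinementResult(chrom, region, region, informative=False,
                                decisions=decisions, haplotype_sizes=sizes)

    # longest run of supporting bins
    best_len = cur_len = 0
    best_end = cur_start = 0
    for k, s in enumerate(support):
        if s:
            cur_len += 1
            if cur_len > best_len:
                best_len, best_end = cur_len, k
        else:
            cur_len = 0
    lo = best_end - best_len + 1
    refined = (int(decisions["start_bp"].iloc[lo]), int(decisions["end_bp"].iloc[best_end]))
    return RefinementResult(chrom, region, refined, informative=True,
                            decisions=decisions, haplotype_sizes=sizes)
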