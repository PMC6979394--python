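"""Genome-wide pairwise epistasis scan for quantitative traits.

Markers are MAF-filtered and LD-pruned, then every remaining pair is tested
with the 1-df interaction term of the linear model
``y ~ gA + gB + gA * gB`` on dosages. A permissive first-pass cut discards
the overwhelming majority of pairs; surviving pairs clustered within a
physical window are reduced to their most significant representative, then
re-fit with population-structure PCs and additive effects to obtain the
adjusted interaction P-value and its incremental variance explained.
Finally, the joint epistatic variance regresses structure- and
additive-corrected residuals on all retained interaction terms at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from mpqtl.binning import BinMap
from mpqtl.io_formats import MISSING, UNKNOWN, GenotypeMatrix

logger = logging.getLogger("mpqtl")

__all__ = [
    "EpiPair",
    "prune_variants",
    "pairwise_scan",
    "adjust_pairs",
    "joint_epistatic_variance",
    "categorize_pairs",
    "recombinant_fraction",
]


@dataclass
class EpiPair:
    chrom_a: str
    pos_a: int
    idx_a: int  # column in the pruned genotype matrix
    chrom_b: str
    pos_b: int
    idx_b: int
    raw_p: float
    adj_p: float | None = None
    pve: float | None = None
    category: str | None = None


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(d: np.ndarray, i: int, j: int) -> float:
    a, b = d[:, i], d[:, j]
    ok = (a != MISSING) & (b != MISSING)
    a = a[ok].astype(float)
    b = b[ok].astype(float)
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def prune_variants(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.02,
    r2_max: float = 0.5,
    window_bp: int = 50_000,
    step_snps: int = 5,
) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning after a MAF filter.

    Within each ``window_bp`` window (anchored at successive retained SNPs,
    advancing ``step_snps`` at a time), the later member of any pair with
    r2 >= ``r2_max`` is removed.
    """
    geno = genotypes.subset_markers(genotypes.maf() >= maf_min)
    d = geno.dosage
    chroms = geno.markers["chrom"].to_numpy(str)
    pos = geno.markers["pos"].to_numpy(np.int64)
    keep = np.ones(geno.n_markers, dtype=bool)
    s = 0
    while s < geno.n_markers:
        if not keep[s]:
            s += 1
            continue
        in_win = np.flatnonzero(
            keep & (chroms == chroms[s]) & (pos >= pos[s]) & (pos <= pos[s] + window_bp)
        )
        for ii in range(len(in_win)):
            i = in_win[ii]
            if not keep[i]:
                continue
            for j in in_win[ii + 1:]:
                if keep[j] and _pairwise_r2(d, i, j) >= r2_max:
                    keep[j] = False
        s += step_snps
    return geno.subset_markers(keep)


# ---------------------------------------------------------------------------
# Interaction tests
# ---------------------------------------------------------------------------

def _interaction_test(y: np.ndarray, cols: np.ndarray) -> float:
    """P-value of the last column's coefficient in OLS of y on [1, cols]."""
    n = len(y)
    X = np.column_stack((np.ones(n), cols))
    p = X.shape[1]
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return np.nan
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - p
    if dof <= 0:
        return np.nan
    s2 = float(resid @ resid) / dof
    se = np.sqrt(s2 * XtX_inv[-1, -1])
    if se == 0 or not np.isfinite(se):
        return np.nan
    t = beta[-1] / se
    return float(2 * stats.t.sf(abs(t), dof))


def pairwise_scan(
    pruned: GenotypeMatrix,
    phenotype,
    first_pass_p: float = 6e-16,
    dedup_window_bp: int = 100_000,
) -> list[EpiPair]:
    """Scan all marker pairs; keep pairs passing the first-pass cut.

    Surviving pairs whose two endpoints both fall within
    ``dedup_window_bp`` of another surviving pair's endpoints form a
    cluster; only the most significant pair per cluster is retained.
    Monomorphic markers are skipped. The test is symmetric in (A, B).
    """
    y = np.asarray(phenotype, dtype=float)
    d = pruned.dosage.astype(float)
    d[d == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    ii, jj = np.where(np.isnan(d))
    d[ii, jj] = mean[jj]
    poly = d.std(axis=0) > 0
    chroms = pruned.markers["chrom"].to_numpy(str)
    pos = pruned.markers["pos"].to_numpy(np.int64)
    S = pruned.n_markers
    survivors: list[EpiPair] = []
    for a in range(S):
        if not poly[a]:
            continue
        for b in range(a + 1, S):
            if not poly[b]:
                continue
            w = d[:, a] * d[:, b]
            if w.std() == 0:
                continue
            pval = _interaction_test(y, np.column_stack((d[:, a], d[:, b], w)))
            if np.isnan(pval) or pval > first_pass_p:
                continue
            survivors.append(EpiPair(
                chrom_a=chroms[a], pos_a=int(pos[a]), idx_a=a,
                chrom_b=chroms[b], pos_b=int(pos[b]), idx_b=b,
                raw_p=pval,
            ))
    return _dedup_pairs(survivors, dedup_window_bp)


def _dedup_pairs(pairs: list[EpiPair], window_bp: int) -> list[EpiPair]:
    """Keep the minimum-P representative of each cluster of nearby pairs."""
    n = len(pairs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = pairs[i], pairs[j]
            close = (
                a.chrom_a == b.chrom_a and a.chrom_b == b.chrom_b
                and abs(a.pos_a - b.pos_a) <= window_bp
                and abs(a.pos_b - b.pos_b) <= window_bp
            )
            if close:
                parent[find(i)] = find(j)
    best: dict[int, EpiPair] = {}
    for i, pair in enumerate(pairs):
        root = find(i)
        if root not in best or pair.raw_p < best[root].raw_p:
            best[root] = pair
    return sorted(best.values(), key=lambda p: (p.chrom_a, p.pos_a, p.chrom_b, p.pos_b))


def adjust_pairs(
    pairs: list[EpiPair],
    pruned: GenotypeMatrix,
    phenotype,
    pcs: np.ndarray | None = None,
    final_p: float = 1e-12,
) -> list[EpiPair]:
    """Re-test pairs controlling for population structure and additive effects.

    Per pair the model ``y ~ PCs + gA + gB + gA*gB`` is refit; the adjusted
    P is the interaction-term test and the pair's PVE is the incremental
    R-squared of the interaction term. Pairs with adjusted P below
    ``final_p`` are kept; rank-deficient fits are dropped with a log entry.
    """
    y = np.asarray(phenotype, dtype=float)
    d = pruned.dosage.astype(float)
    d[d == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    ii, jj = np.where(np.isnan(d))
    d[ii, jj] = mean[jj]
    base = np.empty((len(y), 0)) if pcs is None else np.asarray(pcs, float)
    kept: list[EpiPair] = []
    tss = float(((y - y.mean()) ** 2).sum())
    for pair in pairs:
        ga, gb = d[:, pair.idx_a], d[:, pair.idx_b]
        w = ga * gb
        cols = np.column_stack((base, ga, gb, w))
        X = np.column_stack((np.ones(len(y)), cols))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            logger.warning("dropping rank-deficient pair %s:%d x %s:%d",
                           pair.chrom_a, pair.pos_a, pair.chrom_b, pair.pos_b)
            continue
        pval = _interaction_test(y, cols)
        rss_full = _rss(y, X)
        rss_add = _rss(y, X[:, :-1])
        pair.adj_p = pval
        pair.pve = max(0.0, (rss_add - rss_full) / tss) if tss > 0 else 0.0
        if pval is not None and not np.isnan(pval) and pval < final_p:
            kept.append(pair)
    return kept


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def joint_epistatic_variance(
    pairs: list[EpiPair],
    pruned: GenotypeMatrix,
    phenotype,
    pcs: np.ndarray | None = None,
) -> float:
    """Trait variance jointly explained by all retained interaction terms.

    Population structure and the additive dosages of every involved marker
    are regressed out first; the returned value is the R-squared of the
    residuals on all interaction product terms jointly. When the number of
    terms exceeds half the sample size, only the most significant terms up
    to n/2 are kept (with a warning).
    """
    if not pairs:
        return 0.0
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if len(pairs) > n // 2:
        import warnings

        warnings.warn("more interaction terms than n/2: truncating to the most significant")
        pairs = sorted(pairs, key=lambda p: (p.adj_p if p.adj_p is not None else p.raw_p))
        pairs = pairs[: n // 2]
    d = pruned.dosage.astype(float)
    d[d == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    ii, jj = np.where(np.isnan(d))
    d[ii, jj] = mean[jj]
    involved = sorted({p.idx_a for p in pairs} | {p.idx_b for p in pairs})
    base_cols = [np.ones(n)]
    if pcs is not None:
        base_cols.append(np.asarray(pcs, float))
    base_cols.append(d[:, involved])
    B = np.column_stack(base_cols)
    W = np.column_stack([d[:, p.idx_a] * d[:, p.idx_b] for p in pairs])
    rss_base = _rss(y, B)
    rss_full = _rss(y, np.column_stack((B, W)))
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    return max(0.0, (rss_base - rss_full) / tss)


def categorize_pairs(pairs: list[EpiPair], sqtl_catalog, link_bp: int = 50_000):
    """Assign SS-1 / SS-2 / SN / NN categories by sQTL linkage.

    A side is linked to an sQTL when it lies within ``link_bp`` of the sQTL
    interval. SS-1: both sides linked to sQTL of a shared trait; SS-2: both
    linked but to sQTL of different traits only; SN: exactly one side
    linked; NN: neither. Returns (pairs, fraction dict).
    """
    def hits(chrom: str, pos: int) -> set[str]:
        traits = set()
        for q in sqtl_catalog:
            if q.chrom == chrom and q.start_bp - link_bp <= pos <= q.end_bp + link_bp:
                traits.add(q.trait)
        return traits

    counts = {"SS-1": 0, "SS-2": 0, "SN": 0, "NN": 0}
    for pair in pairs:
        ta = hits(pair.chrom_a, pair.pos_a)
        tb = hits(pair.chrom_b, pair.pos_b)
        if ta and tb:
            pair.category = "SS-1" if ta & tb else "SS-2"
        elif ta or tb:
            pair.category = "SN"
        else:
            pair.category = "NN"
        counts[pair.category] += 1
    total = max(len(pairs), 1)
    fractions = {k: v / total for k, v in counts.items()}
    return pairs, fractions


def recombinant_fraction(bins: BinMap, bin_a: int, bin_b: int) -> float:
    """Fraction of lines whose two bins descend from different founders.

    Lines with an UNKNOWN state at either bin are excluded. Used to compare
    interacting distal pairs against matched random pairs.
    """
    a = bins.states[:, bin_a]
    b = bins.states[:, bin_b]
    ok = (a != UNKNOWN) & (b != UNKNOWN)
    if not ok.any():
        return np.nan
    return float((a[ok] != b[ok]).mean())
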