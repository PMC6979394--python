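"""In-silico power studies: HMM founder tracing and sGWAS-vs-hGWAS mapping.

Two experiment drivers. The first reshuffles founder genomes into
pseudoprogeny with a fixed number of recombinant segments, re-traces them
with the HMM and reports the fraction of SNPs assigned their true founder.
The second plants QTL of three allelic architectures (1, 2 or 3 incompletely
linked QTN per bin), simulates traits with geometrically decaying additive
effects (a**n, h2 = 0.8, Vp = 1), runs both association scans at matched
genome-wide thresholds and accumulates detection power and FDR per scenario
and method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from mpqtl.binning import BinMap, bin_kinship
from mpqtl.hgwas import RemlScanner, hgwas_scan, merge_hqtl, permutation_threshold
from mpqtl.ibd_hmm import HmmParams, filter_snps_for_ibd, fit_mosaic, tracing_power
from mpqtl.io_formats import GeneticMap, GenotypeMatrix, MosaicPath
from mpqtl.sgwas import genotype_pca, lmm_scan, snp_kinship
from mpqtl.synthetic_population import FounderPanel, simulate_pseudoprogeny

__all__ = ["PowerReport", "run_hmm_power_study", "run_mapping_power_study"]


@dataclass
class PowerReport:
    scenario: str
    method: str
    power: float
    fdr: float
    n_replicates: int
    n_causal_tested: int
    ci99: tuple[float, float]
    seed: int | None = None
    detections: np.ndarray | None = None  # (n_replicates, n_qtl) booleans


def _binomial_ci99(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    z = stats.norm.ppf(0.995)
    half = z * np.sqrt(max(p * (1 - p), 1e-12) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def run_hmm_power_study(
    founders: FounderPanel,
    gmap: GeneticMap,
    n_lines: int = 100,
    n_segments: int = 180,
    params: HmmParams | None = None,
    seed: int | None = None,
) -> dict:
    """Founder-tracing power on reshuffled pseudoprogeny.

    Simulates ``n_lines`` mosaic lines with ``n_segments`` recombinant
    segments each (allocated to chromosomes proportionally to map length,
    breakpoints placed by local cM density), projects genotypes, re-traces
    founders with the HMM and scores the per-SNP agreement with the
    simulated truth. The report includes per-chromosome power and a
    truth-vs-inferred segment count comparison.
    """
    params = params or HmmParams()
    truth, geno = simulate_pseudoprogeny(founders, gmap, n_lines, n_segments, seed=seed)
    geno = filter_snps_for_ibd(geno)
    _, inferred = fit_mosaic(geno, founders, gmap, params)
    genome = tracing_power(truth, inferred, geno.markers)
    per_chrom = tracing_power(truth, inferred, geno.markers, by_chromosome=True)
    t_segs = np.asarray([truth.n_segments(ln) for ln in truth.lines])
    i_segs = np.asarray([inferred.n_segments(ln) for ln in inferred.lines])
    return {
        "genome_wide_power": genome,
        "per_chromosome_power": per_chrom,
        "mean_segments_truth": float(t_segs.mean()),
        "mean_segments_inferred": float(i_segs.mean()),
        "n_lines": n_lines,
        "n_markers": geno.n_markers,
    }


def _pick_qtn(
    bins: BinMap,
    geno: GenotypeMatrix,
    n_qtl: int,
    k: int,
    rng: np.random.Generator,
    ld_bounds: tuple[float, float] = (0.1, 0.9),
    maf_min: float = 0.05,
    max_tries: int = 50,
) -> tuple[list[int], list[int]]:
    """Choose causal bins and QTN marker columns.

    Returns (causal bin indices, QTN marker columns, bin by bin). QTN within
    a bin are required (best effort) to be incompletely linked with pairwise
    r2 inside ``ld_bounds``.
    """
    chroms = geno.markers["chrom"].to_numpy(str)
    pos = geno.markers["pos"].to_numpy(np.int64)
    maf = geno.maf()
    b_chrom = bins.bins["chrom"].to_numpy(str)
    b_start = bins.bins["start_bp"].to_numpy(np.int64)
    b_end = bins.bins["end_bp"].to_numpy(np.int64)

    eligible = []
    for b in range(bins.n_bins):
        cols = np.flatnonzero(
            (chroms == b_chrom[b]) & (pos >= b_start[b]) & (pos <= b_end[b]) & (maf >= maf_min)
        )
        if len(cols) >= k:
            eligible.append((b, cols))
    if len(eligible) < n_qtl:
        raise ValueError("not enough bins with sufficient informative markers")
    chosen = rng.choice(len(eligible), size=n_qtl, replace=False)

    d = geno.dosage.astype(float)
    causal_bins, qtn_cols = [], []
    for c in chosen:
        b, cols = eligible[c]
        pick = rng.choice(cols, size=k, replace=False)
        if k > 1:
            for _ in range(max_tries):
                r2s = [
                    np.corrcoef(d[:, i], d[:, j])[0, 1] ** 2
                    for ii, i in enumerate(pick) for j in pick[ii + 1:]
                ]
                if all(ld_bounds[0] < r < ld_bounds[1] for r in r2s):
                    break
                pick = rng.choice(cols, size=k, replace=False)
        causal_bins.append(b)
        qtn_cols.append([int(x) for x in pick])
    return causal_bins, qtn_cols



def _mixed_trait(
    dosage: np.ndarray,
    qtn_cols: list[list[int]],
    arch: np.ndarray,
    effect_model: str,
    a: float,
    h2: float,
    vp: float,
    noise: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One trait carrying all three allelic architectures at once.

    ``arch[q]`` is the QTN count (1, 2 or 3) realized at causal bin ``q``.
    Two readings of the geometric effect series are supported, matching the
    two matched-effect comparisons of the power figure:

    * ``"locus"`` — the series runs over loci: locus q contributes genetic
      variance proportional to ``a**(2 r_q)`` (ranks ``r_q`` shuffled across
      loci) regardless of its QTN count, the effect being split equally over
      its incompletely linked QTN. Architectures are compared at matched
      per-locus variance.
    * ``"qtn"`` — the series runs over QTN: every QTN gets an effect
      ``a**r`` from one shuffled rank sequence, so a k-QTN locus accumulates
      about k shares of variance. Architectures are compared at matched
      per-QTN effect.

    The total genetic variance is rescaled to ``h2 * vp`` and the supplied
    residual vector (shared across effect models of one replicate as common
    random numbers) is scaled to the remainder.
    """
    n = dosage.shape[0]
    g = np.zeros(n)
    if effect_model == "locus":
        ranks = rng.permutation(len(qtn_cols)) + 1
        for q, cols in enumerate(qtn_cols):
            comp = dosage[:, cols[: arch[q]]].sum(axis=1)
            comp = comp - comp.mean()
            sd = comp.std()
            if sd > 0:
                g += (a ** ranks[q]) * comp / sd
    elif effect_model == "qtn":
        n_qtn = int(arch.sum())
        ranks = rng.permutation(n_qtn) + 1
        ri = 0
        for q, cols in enumerate(qtn_cols):
            for c in cols[: arch[q]]:
                x = dosage[:, c] - dosage[:, c].mean()
                sd = x.std()
                if sd > 0:
                    g += (a ** ranks[ri]) * x / sd
                ri += 1
    else:
        raise ValueError("effect_model must be 'locus' or 'qtn'")
    vg = g.var()
    if vg > 0:
        g *= np.sqrt(h2 * vp / vg)
    return g + np.sqrt((1 - h2) * vp) * noise


def _chain_positions(pos: np.ndarray, gap: int) -> list[tuple[int, int]]:
    """Cluster sorted positions into intervals split at gaps > ``gap``."""
    if len(pos) == 0:
        return []
    brk = np.flatnonzero(np.diff(pos) > gap)
    out = []
    for seg in np.split(pos, brk + 1):
        out.append((int(seg[0]), int(seg[-1])))
    return out


def run_mapping_power_study(
    genotypes: GenotypeMatrix,
    bins: BinMap,
    n_qtl_per_arch: int = 3,
    architectures: tuple[int, ...] = (1, 2, 3),
    effect_models: tuple[str, ...] = ("locus", "qtn"),
    n_replicates: int = 60,
    h2: float = 0.8,
    vp: float = 1.0,
    a: float = 0.95,
    sgwas_alpha: float = 0.05,
    lrt_cutoff: float | None = None,
    n_threshold_perms: int = 30,
    window_bp: int = 200_000,
    n_pcs: int = 10,
    seed: int | None = None,
) -> list[PowerReport]:
    """Power/FDR of both scans under biallelic, 4-allelic and 9-allelic QTL.

    Per replicate one trait carries ``n_qtl_per_arch`` causal bins of every
    architecture simultaneously (1, 2 or 3 incompletely linked QTN per bin)
    with h2 = 0.8 and Vp = 1; the residual noise and causal-bin draw are
    shared across effect models as common random numbers. sGWAS runs at the
    Bonferroni cutoff ``sgwas_alpha / n_tested_markers``; hGWAS at
    ``lrt_cutoff`` (derived once by permutation of a null trait when not
    given). A causal bin counts as detected when a declared locus lies
    within ``window_bp`` of it; declared loci with no causal bin within the
    window count as false discoveries.
    """
    rng = np.random.default_rng(seed)
    K = snp_kinship(genotypes)
    pcs = genotype_pca(genotypes, k=min(n_pcs, genotypes.n_samples - 1))
    Kbin = bin_kinship(bins)

    if lrt_cutoff is None:
        null_y = rng.normal(size=genotypes.n_samples)
        lrt_cutoff = permutation_threshold(
            bins, null_y, Kbin, pcs, n_perm=n_threshold_perms, alpha=0.05,
            seed=int(rng.integers(2**31 - 1)),
        )

    maf = genotypes.maf()
    n_tested = int((maf >= 0.02).sum())
    p_cut = sgwas_alpha / max(n_tested, 1)

    b_start = bins.bins["start_bp"].to_numpy(np.int64)
    b_end = bins.bins["end_bp"].to_numpy(np.int64)
    b_chrom = bins.bins["chrom"].to_numpy(str)

    scanner = RemlScanner(Kbin, np.zeros(genotypes.n_samples), pcs)
    names = {1: "biallelic", 2: "4-allelic", 3: "9-allelic"}
    methods = ("sGWAS", "hGWAS")
    n_qtl = n_qtl_per_arch * len(architectures)
    k_max = max(architectures)
    det = {(mo, k, m): np.zeros((n_replicates, n_qtl_per_arch), dtype=bool)
           for mo in effect_models for k in architectures for m in methods}
    declared = {(mo, m): 0 for mo in effect_models for m in methods}
    false = {(mo, m): 0 for mo in effect_models for m in methods}
    dosage = genotypes.dosage.astype(float)

    for rep in range(n_replicates):
        causal_bins, qtn_cols = _pick_qtn(bins, genotypes, n_qtl, k_max, rng)
        arch = np.repeat(architectures, n_qtl_per_arch)
        rng.shuffle(arch)
        noise = rng.standard_normal(genotypes.n_samples)
        rank_seed = int(rng.integers(2**31 - 1))
        windows = [
            (b_chrom[b], b_start[b] - window_bp, b_end[b] + window_bp)
            for b in causal_bins
        ]

        def in_window(chrom, lo, hi):
            return any(c == chrom and lo <= e and hi >= s for c, s, e in windows)

        for mo in effect_models:
            y = _mixed_trait(dosage, qtn_cols, arch, mo, a, h2, vp, noise,
                             np.random.default_rng(rank_seed))

            assoc = lmm_scan(genotypes, y, K, pcs, maf_min=0.02)
            sig = assoc.frame()
            sig = sig[sig["p"] <= p_cut]
            loci_s = []
            for chrom, sub in sig.groupby("chrom", sort=False):
                loci_s += [(str(chrom), lo, hi) for lo, hi in
                           _chain_positions(np.sort(sub["pos"].to_numpy()), window_bp)]

            scanner.set_phenotype(y)
            lrt = hgwas_scan(bins, y, Kbin, pcs, scanner=scanner)
            hqtl = merge_hqtl(bins, lrt, lrt_cutoff)
            loci_h = [(q.chrom, q.start_bp, q.end_bp) for q in hqtl]

            arch_counter = {k: 0 for k in architectures}
            for method, loci in zip(methods, (loci_s, loci_h)):
                declared[mo, method] += len(loci)
                false[mo, method] += sum(not in_window(*loc) for loc in loci)
            for q, b in enumerate(causal_bins):
                k = int(arch[q])
                slot = arch_counter[k]
                arch_counter[k] += 1
                for method, loci in zip(methods, (loci_s, loci_h)):
                    det[mo, k, method][rep, slot] = any(
                        c == b_chrom[b]
                        and lo <= b_end[b] + window_bp
                        and hi >= b_start[b] - window_bp
                        for c, lo, hi in loci
                    )

    reports: list[PowerReport] = []
    for mo in effect_models:
        for k in architectures:
            for method in methods:
                hits = int(det[mo, k, method].sum())
                tot = n_replicates * n_qtl_per_arch
                n_decl = declared[mo, method]
                reports.append(PowerReport(
                    scenario=f"{names[k]}/{mo}", method=method,
                    power=hits / tot,
                    fdr=false[mo, method] / n_decl if n_decl else 0.0,
                    n_replicates=n_replicates, n_causal_tested=tot,
                    ci99=_binomial_ci99(hits, tot), seed=seed,
                    detections=det[mo, k, method],
                ))
    return reports
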