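"""Synthetic multiparent populations: founders, pedigrees, mosaics, phenotypes.

This module generates data with the statistical structure that the downstream
analyses assume: a panel of fully homozygous founder inbreds, progeny genomes
that are mosaics of founder segments produced either by an explicit
pedigree (diallel inter-cross followed by open pollination and selfing by
single seed descent) or by direct segment reshuffling ("pseudoprogeny"), and
quantitative phenotypes driven by additive QTN effects that decay as a
geometric series ``a**n`` with optional pairwise epistatic terms.

Crossovers are placed without interference: per meiosis the crossover count
on a chromosome is Poisson with mean equal to its genetic length in Morgans,
and positions are drawn uniformly on the cM scale (so breakpoint density
follows the local recombination rate of the map). This Markovian breakpoint
process matches the exponential segment-length assumption of the IBD HMM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mpqtl.io_formats import GeneticMap, GenotypeMatrix, MosaicPath, PhenotypeTable

__all__ = [
    "FounderPanel",
    "QtnSpec",
    "make_uniform_map",
    "simulate_founders",
    "simulate_pedigree_population",
    "simulate_pseudoprogeny",
    "simulate_phenotype",
]


@dataclass
class FounderPanel:
    """Haploid allele matrix for a panel of homozygous founder inbreds.

    ``alleles`` is an ``(n_founders, n_markers)`` array in {0, 1}; founders
    are fully homozygous so one haplotype per founder suffices. Marker
    coordinates are shared with a :class:`~mpqtl.io_formats.GeneticMap`.
    """

    founders: list[str]
    alleles: np.ndarray
    markers: pd.DataFrame  # chrom, pos, ref, alt

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or len(self.founders) != self.alleles.shape[0]:
            raise ValueError("alleles must be (n_founders, n_markers)")
        if self.alleles.shape[0] < 2:
            raise ValueError("need at least 2 founders")
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("founder alleles must be haploid 0/1 (no missing)")

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def marker_positions(self, chrom: str) -> np.ndarray:
        return self.markers.loc[self.markers["chrom"] == chrom, "pos"].to_numpy(np.int64)

    def marker_mask(self, chrom: str) -> np.ndarray:
        return (self.markers["chrom"] == chrom).to_numpy()


@dataclass
class QtnSpec:
    """Causal-variant specification for phenotype simulation.

    Additive effects follow the geometric series ``a**rank``; raw genetic
    values are rescaled so the realized genetic variance equals ``h2 * vp``,
    and the residual draws have variance ``(1 - h2 - sum(epi shares)) * vp``.
    ``epistatic_pairs`` lists ``(index_a, index_b, variance_share)`` product
    terms between QTN dosages, each scaled to its requested share of ``vp``.
    """

    markers: list[int]
    ranks: list[int] | None = None
    a: float = 0.95
    h2: float = 0.8
    vp: float = 1.0
    epistatic_pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self):
        if not 0 < self.a < 1:
            raise ValueError("effect decay base a must be in (0, 1)")
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")
        if self.vp <= 0:
            raise ValueError("vp must be positive")
        if self.ranks is None:
            self.ranks = list(range(1, len(self.markers) + 1))
        if len(self.ranks) != len(self.markers):
            raise ValueError("one rank per QTN marker required")
        epi = sum(s for _, _, s in self.epistatic_pairs)
        if self.h2 + epi > 1 + 1e-12:
            raise ValueError("h2 plus epistatic shares exceed 1")

    def effects(self) -> np.ndarray:
        return np.asarray([self.a ** n for n in self.ranks])


# ---------------------------------------------------------------------------
# Fixture genome
# ---------------------------------------------------------------------------

def make_uniform_map(
    n_chrom: int = 2,
    length_cm: float = 100.0,
    length_bp: int = 10_000_000,
    n_markers: int = 5000,
) -> GeneticMap:
    """Build a uniform-rate genetic map whose knots double as SNP markers.

    The default genome (2 chromosomes x 100 cM x 10 Mb with 5000 markers
    each) is small enough that every downstream analysis runs in seconds
    while leaving enough markers per segment for confident IBD tracing.
    """
    rows = []
    for c in range(1, n_chrom + 1):
        pos = np.linspace(1, length_bp, n_markers).astype(np.int64)
        pos = np.unique(pos)
        cm = (pos - 1) / (length_bp - 1) * length_cm
        rows.append(pd.DataFrame({
            "marker_id": [f"chr{c}_{p}" for p in pos],
            "chrom": str(c), "pos_bp": pos, "cM": cm,
        }))
    return GeneticMap(pd.concat(rows, ignore_index=True))


def map_markers(gmap: GeneticMap) -> pd.DataFrame:
    """Marker table (chrom, pos, ref, alt) at the map knots."""
    return pd.DataFrame({
        "chrom": gmap.table["chrom"].astype(str),
        "pos": gmap.table["pos_bp"].astype(np.int64),
        "ref": "A",
        "alt": "T",
    })


# ---------------------------------------------------------------------------
# Founder panel simulation
# ---------------------------------------------------------------------------

def simulate_founders(
    n_founders: int,
    gmap: GeneticMap,
    divergence: float = 0.6,
    maf_law=None,
    seed: int | None = None,
) -> FounderPanel:
    """Draw founder haplotypes with a target pairwise difference rate.

    Each site carries the minor allele in ``k`` of the ``F`` founders; the
    pairwise difference rate of such a site is ``2k(F-k) / (F(F-1))``. Sites
    mix singleton (``k = 1``) and balanced (``k = F//2``) configurations in
    the proportion that makes the expected pairwise difference rate across
    segregating sites equal ``divergence``; which founders carry the minor
    allele is re-randomized per site. ``divergence = 0`` yields an identical
    (degenerate) panel; values below the singleton floor ``2/F`` are capped
    at that floor. A custom ``maf_law(rng, n_sites, n_founders)`` returning
    per-site carrier counts overrides the mixture.
    """
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    markers = map_markers(gmap)
    S = len(markers)
    F = n_founders
    if F < 2:
        raise ValueError("need at least 2 founders")
    names = [f"F{i:02d}" for i in range(1, F + 1)]
    alleles = np.zeros((F, S), dtype=np.int8)
    if divergence == 0:
        return FounderPanel(names, alleles, markers)

    if maf_law is not None:
        ks = np.asarray(maf_law(rng, S, F), dtype=int)
    else:
        k_bal = F // 2
        rate = lambda k: 2 * k * (F - k) / (F * (F - 1))
        r1, rb = rate(1), rate(k_bal)
        if rb == r1:
            q = 0.0
        else:
            q = np.clip((divergence - r1) / (rb - r1), 0.0, 1.0)
        ks = np.where(rng.random(S) < q, k_bal, 1)
    for s in range(S):
        carriers = rng.choice(F, size=ks[s], replace=False)
        alleles[carriers, s] = 1
    return FounderPanel(names, alleles, markers)


# ---------------------------------------------------------------------------
# Meiosis on segment-represented haplotypes
# ---------------------------------------------------------------------------

def _merge_segments(seg: list[tuple[int, int, int]]) -> np.ndarray:
    out = []
    for start, end, fdr in seg:
        if out and out[-1][2] == fdr:
            out[-1] = (out[-1][0], end, fdr)
        else:
            out.append((start, end, fdr))
    return np.asarray(out, dtype=np.int64)


def _slice_haplotype(seg: np.ndarray, lo: int, hi: int) -> list[tuple[int, int, int]]:
    """Segments of `seg` restricted to [lo, hi] (1-based inclusive)."""
    out = []
    for start, end, fdr in seg:
        s, e = max(int(start), lo), min(int(end), hi)
        if s <= e:
            out.append((s, e, int(fdr)))
    return out


def _meiosis_chrom(hapA: np.ndarray, hapB: np.ndarray, gmap: GeneticMap,
                   chrom: str, rng: np.random.Generator) -> np.ndarray:
    """One gamete chromosome: Poisson crossover count, cM-uniform positions."""
    lo, hi = gmap.extent_bp(chrom)
    L_morgan = gmap.length_cm(chrom) / 100.0
    n_xo = rng.poisson(L_morgan)
    if n_xo == 0:
        return (hapA if rng.random() < 0.5 else hapB).copy()
    cm0 = gmap.bp_to_cm(chrom, lo)
    u = np.sort(rng.random(n_xo)) * (gmap.length_cm(chrom)) + cm0
    cuts = np.unique(np.asarray(gmap.cm_to_bp(chrom, u), dtype=np.int64))
    cuts = cuts[(cuts > lo) & (cuts < hi)]
    bounds = np.concatenate(([lo - 1], cuts, [hi]))
    take_a = rng.random() < 0.5
    pieces: list[tuple[int, int, int]] = []
    for i in range(len(bounds) - 1):
        s, e = int(bounds[i]) + 1, int(bounds[i + 1])
        src = hapA if take_a else hapB
        pieces.extend(_slice_haplotype(src, s, e))
        take_a = not take_a
    return _merge_segments(pieces)


def _meiosis(ind, gmap: GeneticMap, rng) -> dict[str, np.ndarray]:
    """Gamete from a diploid individual ``(hap1, hap2)`` of segment dicts."""
    hap1, hap2 = ind
    return {c: _meiosis_chrom(hap1[c], hap2[c], gmap, c, rng) for c in hap1}


def _founder_haplotype(founder: int, gmap: GeneticMap) -> dict[str, np.ndarray]:
    return {
        c: np.asarray([[gmap.extent_bp(c)[0], gmap.extent_bp(c)[1], founder]], dtype=np.int64)
        for c in gmap.chromosomes
    }


def project_genotypes(
    mosaic_pairs: dict[str, tuple[dict, dict]],
    founders: FounderPanel,
    gmap: GeneticMap,
) -> GenotypeMatrix:
    """Project founder alleles through diploid mosaics to SNP dosages."""
    lines = list(mosaic_pairs)
    S = founders.n_markers
    dosage = np.zeros((len(lines), S), dtype=np.int8)
    for chrom in gmap.chromosomes:
        mask = founders.marker_mask(chrom)
        pos = founders.markers.loc[mask, "pos"].to_numpy(np.int64)
        cols = np.flatnonzero(mask)
        for i, line in enumerate(lines):
            for hap in mosaic_pairs[line]:
                seg = hap[chrom]
                idx = np.searchsorted(seg[:, 1], pos)
                states = seg[idx, 2]
                dosage[i, cols] += founders.alleles[states, cols]
    return GenotypeMatrix(samples=lines, markers=founders.markers.copy(), dosage=dosage)


def _haplotype_mosaic(hap_dicts: dict[str, dict[str, np.ndarray]],
                      gmap: GeneticMap) -> MosaicPath:
    extents = {c: gmap.extent_bp(c) for c in gmap.chromosomes}
    return MosaicPath(segments=hap_dicts, extents=extents)


def simulate_pedigree_population(
    founders: FounderPanel,
    gmap: GeneticMap,
    n_lines: int,
    n_intercross_gens: int = 8,
    n_selfing_gens: int = 6,
    seed: int | None = None,
) -> tuple[MosaicPath, GenotypeMatrix]:
    """Simulate a diallel inter-cross population with terminal selfing.

    Generation 1 forms F1s by random pairwise founder crosses omitting selfs
    (complete-diallel style); subsequent inter-cross generations mate random
    distinct parents from the previous generation (open pollination). The
    population is then selfed ``n_selfing_gens`` times by single seed
    descent, halving heterozygosity per generation. Returned genotypes are
    the diploid projection of the final genomes onto founder alleles; the
    truth mosaic records the first of the two transmitted haplotypes (after
    selfing the two differ over only a small residual-heterozygous fraction).

    ``n_intercross_gens = 0`` is a pass-through: each line is a founder F1
    with one whole-chromosome segment per parent and no selfing.
    """
    rng = np.random.default_rng(seed)
    F = founders.n_founders
    for c in gmap.chromosomes:
        if c not in {str(x) for x in founders.markers["chrom"].unique()}:
            raise ValueError(f"chromosome {c} has no markers in the founder panel")

    def f1(i, j):
        return (_founder_haplotype(i, gmap), _founder_haplotype(j, gmap))

    if n_intercross_gens == 0:
        pairs = {}
        for n in range(n_lines):
            i, j = rng.choice(F, size=2, replace=False)
            pairs[f"L{n+1:04d}"] = f1(int(i), int(j))
        truth = _haplotype_mosaic({ln: h1 for ln, (h1, _) in pairs.items()}, gmap)
        return truth, project_genotypes(pairs, founders, gmap)

    # generation 1: all distinct pairwise crosses, cycled to population size
    pop_size = max(n_lines, 2)
    cross_pairs = [(i, j) for i in range(F) for j in range(i + 1, F)]
    rng.shuffle(cross_pairs)
    pop = [f1(*cross_pairs[k % len(cross_pairs)]) for k in range(pop_size)]

    for _ in range(n_intercross_gens - 1):
        nxt = []
        for _ in range(pop_size):
            pa, pb = rng.choice(len(pop), size=2, replace=False)
            nxt.append((_meiosis(pop[pa], gmap, rng), _meiosis(pop[pb], gmap, rng)))
        pop = nxt

    lines = pop[:n_lines]
    for _ in range(n_selfing_gens):
        lines = [(_meiosis(ind, gmap, rng), _meiosis(ind, gmap, rng)) for ind in lines]

    pairs = {f"L{n+1:04d}": ind for n, ind in enumerate(lines)}
    truth = _haplotype_mosaic({ln: h1 for ln, (h1, _) in pairs.items()}, gmap)
    return truth, project_genotypes(pairs, founders, gmap)


# ---------------------------------------------------------------------------
# Pseudoprogeny: direct segment reshuffling
# ---------------------------------------------------------------------------

def _allocate_segments(gmap: GeneticMap, n_segments: int) -> dict[str, int]:
    """Largest-remainder allocation proportional to map length, >=1 each."""
    chroms = gmap.chromosomes
    if n_segments < len(chroms):
        raise ValueError("need at least one segment per chromosome")
    lengths = np.asarray([gmap.length_cm(c) for c in chroms], dtype=float)
    quota = lengths / lengths.sum() * n_segments
    counts = np.maximum(np.floor(quota).astype(int), 1)
    rem = quota - np.floor(quota)
    while counts.sum() < n_segments:
        i = int(np.argmax(rem))
        counts[i] += 1
        rem[i] = -1
    while counts.sum() > n_segments:
        i = int(np.argmax(np.where(counts > 1, rem, -np.inf)))
        counts[i] -= 1
        rem[i] = -1
    return dict(zip(chroms, counts.tolist()))


def simulate_pseudoprogeny(
    founders: FounderPanel,
    gmap: GeneticMap,
    n_lines: int = 100,
    n_segments: int = 180,
    seed: int | None = None,
) -> tuple[MosaicPath, GenotypeMatrix]:
    """Reshuffle founder genomes into mosaic lines with a fixed segment count.

    Per line, ``n_segments`` recombinant segments are allocated to
    chromosomes proportionally to genetic map length; breakpoints are drawn
    uniformly on the cM scale (density proportional to local recombination
    rate) and founders are assigned uniformly at random per segment with
    adjacent labels forced distinct. Genotypes are the homozygous projection
    of founder alleles (dosage 0/2).
    """
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    rng = np.random.default_rng(seed)
    alloc = _allocate_segments(gmap, n_segments)
    F = founders.n_founders
    segments: dict[str, dict[str, np.ndarray]] = {}
    pairs = {}
    for n in range(n_lines):
        line = f"P{n+1:03d}"
        hap: dict[str, np.ndarray] = {}
        for chrom, n_seg in alloc.items():
            lo, hi = gmap.extent_bp(chrom)
            cm0 = gmap.bp_to_cm(chrom, lo)
            # resample until breakpoints are distinct in bp
            while True:
                u = np.sort(rng.random(n_seg - 1)) * gmap.length_cm(chrom) + cm0
                cuts = np.unique(np.asarray(gmap.cm_to_bp(chrom, u), np.int64))
                cuts = cuts[(cuts > lo) & (cuts < hi)]
                if len(cuts) == n_seg - 1:
                    break
            bounds = np.concatenate(([lo - 1], cuts, [hi]))
            labels = np.empty(n_seg, dtype=np.int64)
            labels[0] = rng.integers(F)
            for k in range(1, n_seg):
                step = rng.integers(1, F)  # uniform over the F-1 other founders
                labels[k] = (labels[k - 1] + step) % F
            hap[chrom] = np.column_stack((bounds[:-1] + 1, bounds[1:], labels))
        segments[line] = hap
        pairs[line] = (hap, hap)  # fully homozygous
    truth = _haplotype_mosaic(segments, gmap)
    return truth, project_genotypes(pairs, founders, gmap)


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

def simulate_phenotype(
    genotypes,
    qtn: QtnSpec,
    n_env: int = 1,
    env_var: float = 0.0,
    seed: int | None = None,
    samples: list[str] | None = None,
    trait: str = "trait",
) -> PhenotypeTable:
    """Simulate a quantitative trait from QTN dosages.

    ``genotypes`` is a :class:`GenotypeMatrix` or a raw ``(n, S)`` dosage
    array; QTN columns are indexed by ``qtn.markers``. Additive effects
    ``a**rank`` on centered dosages are rescaled so the realized genetic
    variance is ``h2 * vp`` exactly; each epistatic product term is rescaled
    to its requested variance share; residuals are i.i.d. normal with the
    remaining variance. With ``n_env > 1`` each environment receives a random
    main effect and independent replicate noise, both of variance
    ``env_var``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(genotypes, GenotypeMatrix):
        dosage = genotypes.dosage.astype(float)
        if samples is None:
            samples = list(genotypes.samples)
    else:
        dosage = np.asarray(genotypes, dtype=float)
        if samples is None:
            samples = [f"L{i+1:04d}" for i in range(dosage.shape[0])]
    idx = np.asarray(qtn.markers, dtype=int)
    if idx.size and idx.max() >= dosage.shape[1]:
        raise ValueError("QTN marker index out of range")
    X = dosage[:, idx]
    X = X - X.mean(axis=0)
    g = X @ qtn.effects()
    vg = g.var()
    if vg == 0 and idx.size:
        raise ValueError("all QTN monomorphic: zero genetic variance")
    if vg > 0:
        g = g * np.sqrt(qtn.h2 * qtn.vp / vg)

    epi_total = 0.0
    for ia, ib, share in qtn.epistatic_pairs:
        w = dosage[:, ia] * dosage[:, ib]
        w = w - w.mean()
        vw = w.var()
        if vw == 0:
            raise ValueError("epistatic product term has zero variance")
        g = g + w * np.sqrt(share * qtn.vp / vw)
        epi_total += share

    resid_var = max(0.0, (1.0 - qtn.h2 - epi_total)) * qtn.vp
    rows = []
    if n_env <= 1:
        y = g + (rng.normal(0.0, np.sqrt(resid_var), len(g)) if resid_var > 0 else 0.0)
        rows.append(pd.DataFrame({"line": samples, "trait": trait, "env": "E1", "value": y}))
    else:
        for e in range(n_env):
            delta = rng.normal(0.0, np.sqrt(env_var)) if env_var > 0 else 0.0
            noise = rng.normal(0.0, np.sqrt(resid_var + env_var), len(g)) \
                if (resid_var + env_var) > 0 else np.zeros(len(g))
            rows.append(pd.DataFrame({
                "line": samples, "trait": trait, "env": f"E{e+1}",
                "value": g + delta + noise,
            }))
    return PhenotypeTable(pd.concat(rows, ignore_index=True))


def true_genetic_values(genotypes, qtn: QtnSpec) -> np.ndarray:
    """Noise-free additive genetic values under a QTN spec (for validation)."""
    dosage = genotypes.dosage.astype(float) if isinstance(genotypes, GenotypeMatrix) \
        else np.asarray(genotypes, float)
    X = dosage[:, np.asarray(qtn.markers, int)]
    X = X - X.mean(axis=0)
    g = X @ qtn.effects()
    vg = g.var()
    if vg > 0:
        g = g * np.sqrt(qtn.h2 * qtn.vp / vg)
    return g
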