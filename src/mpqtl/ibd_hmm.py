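"""Founder-mosaic reconstruction by a forward-backward hidden Markov model.

Each progeny line's genome is modelled as a mosaic of founder
identity-by-descent (IBD) segments. Hidden states are the F founders; the
chain starts uniform over founders, and between adjacent markers at genetic
distance d Morgans a switch event occurs with probability 1 - exp(-G * d),
where G is the effective number of accumulated inter-cross generations. On a
switch the new state is re-drawn over founders, so marginal segment lengths
are exponential with mean close to rho / G (rho = genetic length). Emissions
compare the progeny's homozygous allele with each founder's allele under a
symmetric per-site error rate epsilon; heterozygous and missing progeny
calls are uninformative. Posteriors come from the scaled forward-backward
recursion; a founder is called at a SNP only when its posterior exceeds
``call_factor`` times the chance expectation 1/F, otherwise the site is
assigned the UNKNOWN state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mpqtl.io_formats import (
    MISSING,
    UNKNOWN,
    GeneticMap,
    GenotypeMatrix,
    MosaicPath,
)
from mpqtl.synthetic_population import FounderPanel

__all__ = ["HmmParams", "filter_snps_for_ibd", "fit_mosaic", "tracing_power"]


@dataclass
class HmmParams:
    """Tuning parameters of the founder-tracing HMM.

    G:
        Effective number of inter-cross generations driving the switch rate
        per Morgan (default 9: eight rounds of inter-crossing plus roughly
        one more contributed by six generations of selfing).
    epsilon:
        Per-site emission error probability in [0, 0.5).
    call_factor:
        Posterior call multiplier; a founder is called only when its
        posterior exceeds ``call_factor / F``.
    redraw:
        "any" re-draws the post-switch state uniformly over all founders
        (self-switch allowed); "distinct" forces a different founder.
    """

    G: float = 9.0
    epsilon: float = 0.02
    call_factor: float = 2.0
    redraw: str = "any"

    def __post_init__(self):
        if self.G <= 0:
            raise ValueError("G must be positive")
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        if self.redraw not in ("any", "distinct"):
            raise ValueError("redraw must be 'any' or 'distinct'")


def filter_snps_for_ibd(
    progeny: GenotypeMatrix,
    het_max: float = 0.10,
    miss_max: float = 0.25,
) -> GenotypeMatrix:
    """Drop markers with excess heterozygosity or missingness across lines.

    Mirrors the pre-tracing SNP quality filter: markers whose heterozygous
    fraction exceeds ``het_max`` or whose missing-call fraction exceeds
    ``miss_max`` are removed; marker order is preserved.
    """
    d = progeny.dosage
    n = d.shape[0]
    het = (d == 1).sum(axis=0) / n
    miss = (d == MISSING).sum(axis=0) / n
    keep = (het <= het_max) & (miss <= miss_max)
    if not keep.any():
        import warnings

        warnings.warn("all markers removed by the IBD SNP filters")
    return progeny.subset_markers(keep)


def _align_founders(founders: FounderPanel, markers: pd.DataFrame) -> np.ndarray:
    """Column indices of ``markers`` within the founder panel's marker table."""
    key = pd.MultiIndex.from_frame(founders.markers[["chrom", "pos"]])
    want = pd.MultiIndex.from_frame(markers[["chrom", "pos"]])
    idx = key.get_indexer(want)
    if (idx < 0).any():
        raise ValueError("progeny markers missing from the founder panel")
    return idx


def _forward_backward(
    obs_allele: np.ndarray,  # (N, S) in {0, 1, -9}
    founder_alleles: np.ndarray,  # (F, S)
    dist_morgan: np.ndarray,  # (S-1,)
    params: HmmParams,
) -> np.ndarray:
    """Scaled forward-backward; returns posteriors (N, S, F)."""
    N, S = obs_allele.shape
    F = founder_alleles.shape[0]
    eps = params.epsilon
    stay = np.exp(-params.G * np.maximum(dist_morgan, 0.0))
    if np.any(dist_morgan < 0):
        raise ValueError("negative inter-marker map distance")
    switch = 1.0 - stay

    def emission(s: int) -> np.ndarray:
        o = obs_allele[:, s]
        e = np.ones((N, F))
        inf = o >= 0
        if inf.any():
            match = founder_alleles[:, s][None, :] == o[inf][:, None]
            e[inf] = np.where(match, 1.0 - eps, eps)
        return e

    fwd = np.empty((N, S, F))
    scale = np.empty((N, S))
    a = emission(0) / F
    scale[:, 0] = a.sum(axis=1)
    if np.any(scale[:, 0] == 0):
        raise ValueError("observation impossible under every founder (epsilon=0?)")
    fwd[:, 0] = a / scale[:, 0][:, None]
    for s in range(1, S):
        p, q = stay[s - 1], switch[s - 1]
        prev = fwd[:, s - 1]
        if params.redraw == "any":
            pred = p * prev + q / F  # rows of prev sum to 1
        else:
            pred = p * prev + q * (1.0 - prev) / (F - 1)
        a = pred * emission(s)
        scale[:, s] = a.sum(axis=1)
        if np.any(scale[:, s] == 0):
            raise ValueError("observation impossible under every founder (epsilon=0?)")
        fwd[:, s] = a / scale[:, s][:, None]

    post = np.empty((N, S, F))
    b = np.ones((N, F))
    post[:, S - 1] = fwd[:, S - 1]
    for s in range(S - 2, -1, -1):
        p, q = stay[s], switch[s]
        x = emission(s + 1) * b
        if params.redraw == "any":
            b = (p * x + q * x.sum(axis=1)[:, None] / F) / scale[:, s + 1][:, None]
        else:
            b = (p * x + q * (x.sum(axis=1)[:, None] - x) / (F - 1)) / scale[:, s + 1][:, None]
        u = fwd[:, s] * b
        post[:, s] = u / u.sum(axis=1)[:, None]
    return post


def _calls_to_segments(
    calls: np.ndarray, pos: np.ndarray, extent: tuple[int, int]
) -> np.ndarray:
    """Merge consecutive identical per-SNP calls into tiling segments.

    Boundaries between runs fall at the midpoint between flanking markers;
    the first and last segments extend to the chromosome ends.
    """
    lo, hi = extent
    change = np.flatnonzero(calls[1:] != calls[:-1])
    starts = np.empty(len(change) + 1, dtype=np.int64)
    ends = np.empty_like(starts)
    labels = np.empty_like(starts)
    starts[0] = lo
    for k, c in enumerate(change):
        mid = (int(pos[c]) + int(pos[c + 1])) // 2
        ends[k] = mid
        starts[k + 1] = mid + 1
        labels[k] = calls[c]
    ends[-1] = hi
    labels[-1] = calls[-1] if len(calls) else UNKNOWN
    return np.column_stack((starts, ends, labels))


def fit_mosaic(
    progeny: GenotypeMatrix,
    founders: FounderPanel,
    gmap: GeneticMap,
    params: HmmParams | None = None,
) -> tuple[dict[str, np.ndarray], MosaicPath]:
    """Reconstruct founder mosaics for every progeny line.

    Returns ``(posteriors, mosaic)`` where ``posteriors[chrom]`` is an
    ``(n_lines, n_markers_chrom, n_founders)`` posterior array and
    ``mosaic`` carries the called IBD segments (UNKNOWN where no founder's
    posterior clears the call threshold). Progeny markers must be a subset
    of the founder panel's markers; map distances between adjacent retained
    markers are obtained by cM interpolation.
    """
    params = params or HmmParams()
    F = founders.n_founders
    if params.call_factor / F > 1:
        raise ValueError("call threshold call_factor / F exceeds 1")
    col_idx = _align_founders(founders, progeny.markers)

    # observed homozygous allele per line/site; het and missing -> -9
    d = progeny.dosage
    obs = np.full(d.shape, -9, dtype=np.int8)
    obs[d == 0] = 0
    obs[d == 2] = 1

    posteriors: dict[str, np.ndarray] = {}
    seg_by_line: dict[str, dict[str, np.ndarray]] = {ln: {} for ln in progeny.samples}
    chrom_arr = progeny.markers["chrom"].to_numpy(str)
    for chrom in gmap.chromosomes:
        sel = np.flatnonzero(chrom_arr == chrom)
        if sel.size == 0:
            continue
        pos = progeny.markers["pos"].to_numpy(np.int64)[sel]
        cm = np.asarray(gmap.bp_to_cm(chrom, pos), dtype=float)
        dist = np.diff(cm) / 100.0
        fa = founders.alleles[:, col_idx[sel]]
        post = _forward_backward(obs[:, sel], fa, dist, params)
        posteriors[chrom] = post

        # >= so the degenerate F=2 threshold of 1.0 still permits calls
        thr = params.call_factor / F
        best = post.argmax(axis=2)
        maxp = post.max(axis=2)
        calls = np.where(maxp >= thr, best, UNKNOWN).astype(np.int64)
        extent = gmap.extent_bp(chrom)
        for i, line in enumerate(progeny.samples):
            seg_by_line[line][chrom] = _calls_to_segments(calls[i], pos, extent)

    mosaic = MosaicPath(
        segments=seg_by_line,
        extents={c: gmap.extent_bp(c) for c in gmap.chromosomes},
    )
    return posteriors, mosaic


def tracing_power(
    truth: MosaicPath,
    inferred: MosaicPath,
    markers: pd.DataFrame,
    by_chromosome: bool = False,
):
    """Fraction of SNPs whose inferred founder origin matches the truth.

    UNKNOWN calls count as incorrect. ``markers`` is a (chrom, pos) table of
    the SNPs over which power is evaluated. With ``by_chromosome=True`` a
    dict of per-chromosome fractions is returned instead of the genome-wide
    scalar.
    """
    per_chrom: dict[str, float] = {}
    n_total = n_match = 0
    chrom_arr = markers["chrom"].to_numpy(str)
    pos_arr = markers["pos"].to_numpy(np.int64)
    for chrom in truth.chromosomes:
        sel = chrom_arr == chrom
        if not sel.any():
            continue
        pos = pos_arr[sel]
        match = total = 0
        for line in truth.lines:
            t = truth.states_at(chrom, pos, line)
            f = inferred.states_at(chrom, pos, line)
            match += int(((t == f) & (f != UNKNOWN)).sum())
            total += len(pos)
        per_chrom[chrom] = match / total
        n_match += match
        n_total += total
    if by_chromosome:
        return per_chrom
    return n_match / n_total
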