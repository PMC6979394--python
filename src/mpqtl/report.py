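"""Per-trait summaries: heritability partition and QTL co-localization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mpqtl.binning import BinMap
from mpqtl.hgwas import HQtl
from mpqtl.io_formats import GenotypeMatrix
from mpqtl.quantgen import qtl_pve
from mpqtl.sgwas import SQtl, _marker_index

__all__ = ["TraitSummary", "partition_heritability", "colocalize"]


@dataclass
class TraitSummary:
    """Stacked partition of a trait's heritability across QTL classes."""

    trait: str
    h2: float
    n_sqtl: int
    sqtl_frac: float  # joint sQTL PVE as a fraction of H2
    n_hqtl: int
    hqtl_increment_frac: float  # additional fraction captured by hQTL
    epistatic_frac: float
    remainder: float


def _sqtl_predictors(sqtls: list[SQtl], genotypes: GenotypeMatrix) -> list:
    return [("dosage", genotypes.dosage[:, _marker_index(genotypes, q.chrom, q.peak_pos)])
            for q in sqtls]


def _hqtl_predictors(hqtls: list[HQtl], bins: BinMap) -> list:
    return [("states", bins.states[:, q.peak_bin]) for q in hqtls]


def partition_heritability(
    sqtls: list[SQtl],
    hqtls: list[HQtl],
    phenotype,
    genotypes: GenotypeMatrix,
    bins: BinMap,
    h2: float,
    epistatic_variance: float = 0.0,
    trait: str = "trait",
) -> TraitSummary:
    """Partition H2 into sQTL, incremental hQTL and unexplained components.

    The joint sQTL PVE comes from a multiple regression of the line values
    on all sQTL peak-SNP dosages; the hQTL increment is the gain in joint
    R-squared when all hQTL peak-bin state factors are added. Components are
    expressed as fractions of ``h2``; the remainder is what neither class
    (nor the supplied epistatic variance) accounts for.
    """
    if h2 <= 0:
        raise ValueError("h2 must be positive")
    y = np.asarray(phenotype, dtype=float)
    preds_s = _sqtl_predictors(sqtls, genotypes)
    preds_h = _hqtl_predictors(hqtls, bins)
    _, joint_s = qtl_pve(y, preds_s)
    _, joint_sh = qtl_pve(y, preds_s + preds_h)
    sqtl_frac = joint_s / h2
    hqtl_frac = max(0.0, (joint_sh - joint_s) / h2)
    epi_frac = epistatic_variance / h2
    remainder = max(0.0, 1.0 - sqtl_frac - hqtl_frac - epi_frac)
    return TraitSummary(
        trait=trait, h2=h2, n_sqtl=len(sqtls), sqtl_frac=sqtl_frac,
        n_hqtl=len(hqtls), hqtl_increment_frac=hqtl_frac,
        epistatic_frac=epi_frac, remainder=remainder,
    )


def _overlaps(a_start, a_end, b_start, b_end, slack: int) -> bool:
    return a_start <= b_end + slack and b_start <= a_end + slack


def colocalize(
    sqtls: list[SQtl],
    hqtls: list[HQtl],
    slack_bp: int = 0,
) -> tuple[int, int, int]:
    """Venn counts of physical co-localization between sQTL and hQTL.

    Two loci co-localize when their intervals overlap by at least 1 bp
    (optionally padded by ``slack_bp``) on the same chromosome for the same
    trait. Returns (s_only, shared, h_only) where ``shared`` counts sQTL
    with at least one co-localizing hQTL.
    """
    shared = 0
    matched_h = set()
    for q in sqtls:
        hit = False
        for i, h in enumerate(hqtls):
            if q.trait == h.trait and q.chrom == h.chrom and \
                    _overlaps(q.start_bp, q.end_bp, h.start_bp, h.end_bp, slack_bp):
                hit = True
                matched_h.add(i)
        shared += hit
    s_only = len(sqtls) - shared
    h_only = len(hqtls) - len(matched_h)
    return s_only, shared, h_only
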