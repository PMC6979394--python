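"""Recombination bins: genome partition at all breakpoints, and bin kinship.

A *bin* is a maximal genomic span within which no recombination breakpoint
occurs in any line of the population, so every line carries a single founder
IBD state per bin. Bins are the unit of haplotype-based association testing,
and the bin-state indicator matrix also yields the kinship used as the
polygenic covariance in that scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mpqtl.io_formats import UNKNOWN, MosaicPath

__all__ = ["BinMap", "build_bins", "bin_kinship"]


@dataclass
class BinMap:
    """Genome partition into recombination bins with per-line founder states.

    ``bins`` has columns (chrom, start_bp, end_bp), 1-based inclusive and
    tiling each chromosome; ``states[i, b]`` is line i's founder state in
    bin b (UNKNOWN where the mosaic was untraceable).
    """

    bins: pd.DataFrame
    states: np.ndarray
    lines: list[str]

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.shape != (len(self.lines), len(self.bins)):
            raise ValueError("states shape must be (n_lines, n_bins)")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def n_states_per_bin(self) -> np.ndarray:
        """Count of distinct observed (non-UNKNOWN) states per bin."""
        out = np.empty(self.n_bins, dtype=int)
        for b in range(self.n_bins):
            col = self.states[:, b]
            out[b] = len(np.unique(col[col != UNKNOWN]))
        return out

    def lengths_bp(self) -> np.ndarray:
        return (self.bins["end_bp"] - self.bins["start_bp"] + 1).to_numpy(np.int64)

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        for i, line in enumerate(self.lines):
            out[line] = self.states[i]
        return out


def build_bins(mosaics: MosaicPath) -> BinMap:
    """Partition the genome at the union of all lines' segment boundaries.

    Each line's state in a bin is inherited from its covering segment
    (UNKNOWN propagates). Because bin edges include every breakpoint of
    every line, no inferred breakpoint falls strictly inside a bin.
    """
    lines = mosaics.lines
    chrom_frames = []
    state_cols = []
    for chrom in mosaics.chromosomes:
        lo, hi = mosaics.extents[chrom]
        starts = {lo}
        for line in lines:
            seg = mosaics.segments[line][chrom]
            if seg[0, 0] != lo or seg[-1, 1] != hi:
                raise ValueError(f"line {line} does not tile chromosome {chrom}")
            starts.update(int(s) for s in seg[1:, 0])
        bounds = np.asarray(sorted(starts), dtype=np.int64)
        ends = np.concatenate((bounds[1:] - 1, [hi]))
        chrom_frames.append(pd.DataFrame({
            "chrom": chrom, "start_bp": bounds, "end_bp": ends,
        }))
        block = np.empty((len(lines), len(bounds)), dtype=np.int64)
        for i, line in enumerate(lines):
            block[i] = mosaics.states_at(chrom, bounds, line)
        state_cols.append(block)
    bins = pd.concat(chrom_frames, ignore_index=True)
    return BinMap(bins=bins, states=np.concatenate(state_cols, axis=1), lines=list(lines))


def bin_kinship(bins: BinMap, length_weighted: bool = False) -> np.ndarray:
    """Kinship from bin founder states reformatted as dummy variables.

    With Z the line x (bin, state) indicator matrix, K = Z Z' / n_bins, i.e.
    K[i, j] is the fraction of bins where lines i and j carry the same
    founder state. UNKNOWN matches nothing, so the diagonal equals each
    line's fraction of traceable bins. ``length_weighted=True`` weights bins
    by physical length instead of equally.
    """
    if bins.n_bins == 0:
        raise ValueError("empty bin map")
    S = bins.states
    N, B = S.shape
    w = bins.lengths_bp().astype(float) if length_weighted else np.ones(B)
    w = w / w.sum()
    K = np.zeros((N, N))
    for f in np.unique(S[S != UNKNOWN]):
        Z = (S == f).astype(float) * np.sqrt(w)[None, :]
        K += Z @ Z.T
    return K
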