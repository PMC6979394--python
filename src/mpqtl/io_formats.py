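"""Core containers and readers/writers for the external file formats.

Conventions
-----------
* All genomic coordinates are 1-based inclusive internally (VCF-compatible);
  BED export converts to 0-based half-open.
* Missing genotype dosages are encoded by the sentinel ``MISSING`` (-1);
  unassigned founder states by ``UNKNOWN`` (-1).
* Genetic-map positions interpolate piecewise-linearly in bp, clamped at the
  chromosome ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mpqtl")

#: Sentinel for a missing genotype dosage.
MISSING: int = -1
#: Sentinel for an untraceable founder state.
UNKNOWN: int = -1


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

class GeneticMap:
    """Marker bp <-> cM coordinates per chromosome.

    Parameters
    ----------
    table:
        DataFrame with columns ``chrom``, ``pos_bp``, ``cM`` (and optionally
        ``marker_id``). Within each chromosome ``pos_bp`` must be strictly
        increasing and ``cM`` non-decreasing with first value >= 0.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "pos_bp", "cM"}
        if not required.issubset(table.columns):
            raise ValueError(f"genetic map requires columns {sorted(required)}")
        self.table = table.reset_index(drop=True)
        self._bp: dict[str, np.ndarray] = {}
        self._cm: dict[str, np.ndarray] = {}
        for chrom, sub in table.groupby("chrom", sort=False):
            bp = sub["pos_bp"].to_numpy(dtype=np.int64)
            cm = sub["cM"].to_numpy(dtype=float)
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"chromosome {chrom}: pos_bp not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {chrom}: cM decreasing")
            if cm[0] < 0:
                raise ValueError(f"chromosome {chrom}: negative cM")
            self._bp[str(chrom)] = bp
            self._cm[str(chrom)] = cm

    @property
    def chromosomes(self) -> list[str]:
        return list(self._bp)

    def length_cm(self, chrom: str) -> float:
        cm = self._cm[chrom]
        return float(cm[-1] - cm[0])

    def total_length_cm(self) -> float:
        return sum(self.length_cm(c) for c in self.chromosomes)

    def extent_bp(self, chrom: str) -> tuple[int, int]:
        bp = self._bp[chrom]
        return int(bp[0]), int(bp[-1])

    def bp_to_cm(self, chrom: str, pos_bp) -> np.ndarray | float:
        """Interpolate cM at arbitrary bp positions (clamped at map ends)."""
        bp, cm = self._bp[chrom], self._cm[chrom]
        out = np.interp(np.asarray(pos_bp, dtype=float), bp, cm)
        return float(out) if np.isscalar(pos_bp) else out

    def cm_to_bp(self, chrom: str, pos_cm) -> np.ndarray | float:
        """Inverse interpolation; flat map stretches resolve to the left knot."""
        bp, cm = self._bp[chrom], self._cm[chrom]
        out = np.interp(np.asarray(pos_cm, dtype=float), cm, bp)
        if np.isscalar(pos_cm):
            return float(out)
        return out


def read_genetic_map(path) -> GeneticMap:
    """Read a consensus genetic map from TSV with columns chrom, pos_bp, cM."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GeneticMap(table)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Dosage matrix over lines x markers.

    Attributes
    ----------
    samples:
        Line identifiers, one per row of ``dosage``.
    markers:
        DataFrame with columns ``chrom``, ``pos``, ``ref``, ``alt``, sorted by
        (chrom, pos) with one record per position.
    dosage:
        ``(n_samples, n_markers)`` int8 array with values in
        {0, 1, 2, MISSING}.
    """

    samples: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError("dosage shape does not match samples x markers")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values outside {0,1,2,missing}")
        keys = list(zip(self.markers["chrom"], self.markers["pos"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicated (chrom, pos) marker records")
        # chromosomes must form contiguous blocks with increasing positions
        chroms = self.markers["chrom"].astype(str).to_numpy()
        seen: set[str] = set()
        prev = None
        for c in chroms:
            if c != prev and c in seen:
                raise ValueError("markers of one chromosome are not contiguous")
            seen.add(c)
            prev = c
        pos = self.markers["pos"].to_numpy()
        within = chroms[1:] == chroms[:-1]
        if np.any(within & (np.diff(pos) <= 0)):
            raise ValueError("marker positions not increasing within chromosome")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=self.markers.loc[mask].reset_index(drop=True),
            dosage=self.dosage[:, mask],
        )

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker, ignoring missing calls."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        p = d.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(p, 1.0 - p)


def read_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    """Read genotypes from a VCF (biallelic records) or a TSV dosage table.

    Multiallelic VCF records are skipped with a logged count; heterozygous
    calls become dosage 1 and ``./.`` maps to the missing sentinel.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises on malformed headers
        raise ValueError(f"failed to parse VCF header of {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, chroms, poss, refs, alts = [], [], [], [], []
    n_multi = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    code = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        rows.append(code[np.asarray(rec.gt_types)])
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    if n_multi:
        logger.info("skipped %d multiallelic VCF records", n_multi)
    markers = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    order = np.lexsort((markers["pos"], markers["chrom"].astype(str)))
    markers = markers.iloc[order].reset_index(drop=True)
    dosage = np.asarray(rows, dtype=np.int8).T[:, order] if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)


def _read_dosage_tsv(path) -> GenotypeMatrix:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "ref", "alt"]
    if not set(meta_cols).issubset(table.columns):
        raise ValueError(f"dosage TSV requires columns {meta_cols} then one per line")
    samples = [c for c in table.columns if c not in meta_cols]
    dosage = table[samples].to_numpy(dtype=float)
    dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8).T
    return GenotypeMatrix(samples=samples, markers=table[meta_cols].copy(), dosage=dosage)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    """Write the TSV dosage representation (markers as rows, lines as columns)."""
    table = geno.markers.copy()
    dosage = geno.dosage.T.astype(float)
    dosage[dosage == MISSING] = np.nan
    for i, s in enumerate(geno.samples):
        table[s] = dosage[:, i]
    table.to_csv(path, sep="\t", index=False, float_format="%.0f")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Long-format phenotype records: (line, trait, env, value)."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"line", "trait", "value"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"phenotype table requires columns {sorted(required)}")
        if "env" not in self.table.columns:
            self.table = self.table.assign(env="E1")
        dup = self.table.duplicated(subset=["line", "trait", "env"])
        if dup.any():
            raise ValueError("duplicate (line, trait, env) phenotype records")

    def traits(self) -> list[str]:
        return sorted(self.table["trait"].unique())

    def environments(self, trait: str) -> list[str]:
        sub = self.table[self.table["trait"] == trait]
        return sorted(sub["env"].unique())

    def trait_values(self, trait: str, lines: list[str] | None = None) -> pd.Series:
        """Per-line mean across environments for one trait."""
        sub = self.table[self.table["trait"] == trait]
        means = sub.groupby("line")["value"].mean()
        if lines is not None:
            means = means.reindex(lines)
        return means


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path))


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Founder mosaics
# ---------------------------------------------------------------------------

@dataclass
class MosaicPath:
    """Per-line tiling of the genome by founder-labelled IBD segments.

    ``segments[line][chrom]`` is an ``(n_seg, 3)`` int64 array of
    ``(start_bp, end_bp, founder)`` rows with 1-based inclusive coordinates;
    founder ``UNKNOWN`` marks untraceable spans. Segments must tile each
    chromosome exactly and adjacent segments must carry different labels.
    """

    segments: dict[str, dict[str, np.ndarray]]
    extents: dict[str, tuple[int, int]]

    def __post_init__(self):
        for line, chroms in self.segments.items():
            for chrom, seg in chroms.items():
                seg = np.asarray(seg, dtype=np.int64)
                if seg.ndim != 2 or seg.shape[1] != 3:
                    raise ValueError(f"{line}/{chrom}: segments must be (n, 3)")
                lo, hi = self.extents[chrom]
                if seg[0, 0] != lo or seg[-1, 1] != hi:
                    raise ValueError(f"{line}/{chrom}: segments do not span chromosome")
                if np.any(seg[1:, 0] != seg[:-1, 1] + 1):
                    raise ValueError(f"{line}/{chrom}: gap or overlap between segments")
                if np.any(seg[:, 1] < seg[:, 0]):
                    raise ValueError(f"{line}/{chrom}: empty segment")
                if np.any(seg[1:, 2] == seg[:-1, 2]):
                    raise ValueError(f"{line}/{chrom}: adjacent segments share a label")
                chroms[chrom] = seg

    @property
    def lines(self) -> list[str]:
        return list(self.segments)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.extents)

    def n_segments(self, line: str) -> int:
        return sum(len(seg) for seg in self.segments[line].values())

    def states_at(self, chrom: str, pos_bp: np.ndarray, line: str) -> np.ndarray:
        """Founder label at each queried position (positions must be sorted)."""
        seg = self.segments[line][chrom]
        idx = np.searchsorted(seg[:, 1], pos_bp)
        return seg[idx, 2]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for line, chroms in self.segments.items():
            for chrom, seg in chroms.items():
                for start, end, fdr in seg:
                    rows.append((line, chrom, int(start), int(end),
                                 "UNKNOWN" if fdr == UNKNOWN else int(fdr)))
        return pd.DataFrame(rows, columns=["line", "chrom", "start_bp", "end_bp", "founder"])


def read_mosaic(path) -> MosaicPath:
    """Read a mosaic segment TSV (line, chrom, start_bp, end_bp, founder)."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    segments: dict[str, dict[str, np.ndarray]] = {}
    extents: dict[str, tuple[int, int]] = {}
    fdr = table["founder"].replace("UNKNOWN", UNKNOWN).astype(np.int64)
    table = table.assign(founder=fdr)
    for (line, chrom), sub in table.groupby(["line", "chrom"], sort=False):
        seg = sub[["start_bp", "end_bp", "founder"]].to_numpy(dtype=np.int64)
        segments.setdefault(str(line), {})[chrom] = seg
        lo, hi = int(seg[0, 0]), int(seg[-1, 1])
        if chrom in extents:
            extents[chrom] = (min(extents[chrom][0], lo), max(extents[chrom][1], hi))
        else:
            extents[chrom] = (lo, hi)
    return MosaicPath(segments=segments, extents=extents)


def write_mosaic(mosaic: MosaicPath, path) -> None:
    mosaic.to_frame().to_csv(path, sep="\t", index=False)


def segments_to_bed(mosaic: MosaicPath) -> pd.DataFrame:
    """Export segments as 0-based half-open BED records."""
    frame = mosaic.to_frame()
    return pd.DataFrame({
        "chrom": frame["chrom"],
        "start": frame["start_bp"] - 1,
        "end": frame["end_bp"],
        "name": frame["line"].astype(str) + ":" + frame["founder"].astype(str),
    })
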