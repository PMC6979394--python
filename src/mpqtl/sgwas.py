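"""Single-variant mixed-model association scan and sQTL grouping.

The scan fits ``y = X beta + g b + u + eps`` per marker, with X holding an
intercept and the top principal components of the genotype matrix,
``u ~ N(0, sigma2_g K)`` for a SNP-derived kinship K, and Wald tests on the
marker effect b. Variance components are estimated once under the null model
on the eigenbasis of K and then held fixed for every marker (the P3D /
EMMAX approximation); an exact per-marker REML refit is available behind a
flag. Significant SNPs are grouped into sQTL by gap chaining, LD merging and
small-interval extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from mpqtl.io_formats import MISSING, GenotypeMatrix

__all__ = [
    "AssocResult",
    "SQtl",
    "genotype_pca",
    "snp_kinship",
    "lmm_scan",
    "group_sqtl",
    "significance_threshold",
    "marker_r2",
]


@dataclass
class AssocResult:
    """Per-marker effect estimates, standard errors and Wald P-values."""

    markers: pd.DataFrame  # chrom, pos (tested markers only)
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    meta: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        out = self.markers[["chrom", "pos"]].copy()
        out["beta"], out["se"], out["p"] = self.beta, self.se, self.p
        return out


@dataclass
class SQtl:
    """A grouped single-variant QTL: interval, members and peak statistics."""

    trait: str
    chrom: str
    start_bp: int
    end_bp: int
    peak_pos: int
    peak_p: float
    members: list[int]  # significant member SNP positions
    pve: float | None = None


def significance_threshold(alpha: float, n_eff: int) -> float:
    """Bonferroni-style genome-wide cutoff alpha / n_eff over effective tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_eff < 1:
        raise ValueError("n_eff must be >= 1")
    return alpha / n_eff


def _filled_dosage(geno: GenotypeMatrix) -> np.ndarray:
    d = geno.dosage.astype(float)
    d[d == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = mean[idx[1]]
    return d


def genotype_pca(genotypes: GenotypeMatrix, k: int = 10) -> np.ndarray:
    """Top-k PCs of the centered, standardized dosage matrix.

    Deterministic up to sign; the sign of each component is fixed by making
    its largest-magnitude SNP loading positive.
    """
    n = genotypes.n_samples
    if k >= n:
        raise ValueError("k must be smaller than the number of lines")
    d = _filled_dosage(genotypes)
    d -= d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    d /= sd
    U, s, Vt = np.linalg.svd(d, full_matrices=False)
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def snp_kinship(genotypes: GenotypeMatrix) -> np.ndarray:
    """Centered cross-product kinship K = W W' / n_markers."""
    d = _filled_dosage(genotypes)
    d -= d.mean(axis=0)
    return d @ d.T / d.shape[1]


def _emma_delta(y: np.ndarray, X: np.ndarray, lam: np.ndarray, Ut: np.ndarray):
    """Null-model REML estimate of delta = sigma2_e / sigma2_g on K's eigenbasis."""
    n, p = X.shape
    ys, Xs = Ut @ y, Ut @ X

    def neg_restricted_ll(log_delta):
        w = lam + np.exp(log_delta)
        Xw = Xs / w[:, None]
        XtWX = Xs.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ ys)
        r = ys - Xs @ beta
        ypy = float(r @ (r / w))
        sign, ld = np.linalg.slogdet(XtWX)
        if sign <= 0 or ypy <= 0:
            return 1e30
        return 0.5 * ((n - p) * np.log(ypy) + np.log(w).sum() + ld)

    grid = np.linspace(-10, 10, 41)
    vals = [neg_restricted_ll(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(lo, hi), method="bounded")
    return float(np.exp(res.x))


def lmm_scan(
    genotypes: GenotypeMatrix,
    phenotype,
    kinship: np.ndarray,
    pcs: np.ndarray | None = None,
    maf_min: float = 0.02,
    exact: bool = False,
    effect_in_sd: bool = False,
    trait: str = "trait",
) -> AssocResult:
    """Mixed-model scan over all markers with MAF >= ``maf_min``.

    ``phenotype`` is an array or Series of line values aligned with
    ``genotypes.samples``. With ``effect_in_sd=True`` effects are reported in
    trait standard-deviation units.
    """
    y = np.asarray(phenotype, dtype=float)
    n = genotypes.n_samples
    if y.shape != (n,):
        raise ValueError("phenotype length does not match line count")
    lam, U = np.linalg.eigh(kinship)
    if lam.min() < -1e-8:
        raise ValueError(f"kinship not PSD: smallest eigenvalue {lam.min():.3e}")
    lam = np.maximum(lam, 0.0)
    X = np.ones((n, 1)) if pcs is None else np.column_stack((np.ones(n), pcs))
    p = X.shape[1]
    Ut = U.T
    if effect_in_sd:
        y = y / y.std()

    keep = genotypes.maf() >= maf_min
    G = _filled_dosage(genotypes)[:, keep]
    markers = genotypes.markers.loc[keep, ["chrom", "pos"]].reset_index(drop=True)

    delta = _emma_delta(y, X, lam, Ut)
    w = lam + delta
    sw = np.sqrt(w)
    ty, tX, tG = (Ut @ y) / sw, (Ut @ X) / sw[:, None], (Ut @ G) / sw[:, None]

    # project out fixed effects
    Q, _ = np.linalg.qr(tX)
    ry = ty - Q @ (Q.T @ ty)
    rG = tG - Q @ (Q.T @ tG)

    gg = (rG * rG).sum(axis=0)
    gy = rG.T @ ry
    dof = n - p - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = float(ry @ ry) - beta * gy
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / gg)
        tstat = beta / se
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    mono = gg <= 1e-12
    beta[mono], se[mono], pvals[mono] = 0.0, np.inf, 1.0

    if exact:
        for j in range(tG.shape[1]):
            Xj = np.column_stack((X, G[:, j]))
            dj = _emma_delta(y, Xj, lam, Ut)
            wj = np.sqrt(lam + dj)
            tyj, tXj = (Ut @ y) / wj, (Ut @ Xj) / wj[:, None]
            coef, res_, rank, _ = np.linalg.lstsq(tXj, tyj, rcond=None)
            rssj = float(tyj @ tyj - tyj @ (tXj @ coef))
            s2 = rssj / (n - p - 1)
            XtX = np.linalg.inv(tXj.T @ tXj)
            sej = np.sqrt(s2 * XtX[-1, -1])
            beta[j], se[j] = coef[-1], sej
            pvals[j] = 2 * stats.t.sf(abs(coef[-1] / sej), n - p - 1)

    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    return AssocResult(
        markers=markers, beta=beta, se=se, p=pvals,
        meta={"delta": delta, "n_pcs": 0 if pcs is None else pcs.shape[1],
              "maf_min": maf_min, "trait": trait},
    )


def marker_r2(geno: GenotypeMatrix, pos_a: tuple, pos_b: tuple) -> float:
    """Squared Pearson correlation of two markers' dosages (pairwise complete)."""
    ia = _marker_index(geno, *pos_a)
    ib = _marker_index(geno, *pos_b)
    a = geno.dosage[:, ia].astype(float)
    b = geno.dosage[:, ib].astype(float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _marker_index(geno: GenotypeMatrix, chrom, pos) -> int:
    hit = np.flatnonzero(
        (geno.markers["chrom"].to_numpy(str) == str(chrom))
        & (geno.markers["pos"].to_numpy() == pos)
    )
    if len(hit) != 1:
        raise KeyError(f"marker {chrom}:{pos} not found")
    return int(hit[0])


def group_sqtl(
    assoc: AssocResult,
    genotypes: GenotypeMatrix,
    threshold: float = 1.23e-8,
    gap_bp: int = 20_000,
    min_snps: int = 2,
    ld_merge_r2: float = 0.2,
    extend_bp: int = 25_000,
    small_span: int = 50_000,
    strong_factor: float = 100.0,
    trait: str = "trait",
) -> list[SQtl]:
    """Group significant SNPs into sQTL.

    Steps: (1) chain significant SNPs whose consecutive gap is below
    ``gap_bp``; (2) drop chains with fewer than ``min_snps`` members;
    (3) merge adjacent loci when any cross-locus pair of significant SNPs is
    in LD (r2 >= ``ld_merge_r2``); (4) extend both flanks by ``extend_bp``
    for loci spanning less than ``small_span`` whose peak P is below
    ``threshold / strong_factor``. The peak SNP defines the locus
    significance; the interval spans the member positions after extension.
    """
    frame = assoc.frame()
    sig = frame[frame["p"] <= threshold]
    loci: list[dict] = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        pvs = sub["p"].to_numpy()
        brk = np.flatnonzero(np.diff(pos) >= gap_bp)
        for seg in np.split(np.arange(len(pos)), brk + 1):
            if len(seg) < min_snps:
                continue
            loci.append({
                "chrom": str(chrom),
                "members": list(pos[seg]),
                "member_p": list(pvs[seg]),
            })

    # LD merge of adjacent loci per chromosome, repeated to a fixed point
    merged = True
    while merged:
        merged = False
        for i in range(len(loci) - 1):
            a, b = loci[i], loci[i + 1]
            if a["chrom"] != b["chrom"]:
                continue
            linked = any(
                marker_r2(genotypes, (a["chrom"], pa), (b["chrom"], pb)) >= ld_merge_r2
                for pa in a["members"] for pb in b["members"]
            )
            if linked:
                a["members"] += b["members"]
                a["member_p"] += b["member_p"]
                del loci[i + 1]
                merged = True
                break

    out: list[SQtl] = []
    for loc in loci:
        members = sorted(loc["members"])
        pvs = loc["member_p"]
        peak_i = int(np.argmin(pvs))
        peak_pos, peak_p = int(loc["members"][peak_i]), float(pvs[peak_i])
        start, end = int(members[0]), int(members[-1])
        if end - start < small_span and peak_p < threshold / strong_factor:
            start, end = max(1, start - extend_bp), end + extend_bp
        out.append(SQtl(
            trait=trait, chrom=loc["chrom"], start_bp=start, end_bp=end,
            peak_pos=peak_pos, peak_p=peak_p, members=members,
        ))
    return out
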