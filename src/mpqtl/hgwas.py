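"""Bin-haplotype mixed-model scan with REML likelihood-ratio tests.

Each recombination bin is tested by comparing two restricted likelihoods:
the full model ``y = X beta + Z_b a + u + eps`` with a random haplotype
effect ``a ~ N(0, sigma2_b I)`` over the bin's founder-state dummy columns
``Z_b`` and a polygenic term ``u ~ N(0, sigma2_g K)`` with K the bin-based
kinship, against the null model without ``Z_b``. Fixed effects (intercept
plus top PCs) are identical in both models so the REML comparison is valid;
LRT = 2 * (logL_full - logL_null), floored at zero.

The solver works on the eigenbasis of K with the residual variance profiled
out. The polygenic-to-residual ratio is estimated once under the null and,
by default, held there while the haplotype variance ratio is maximized by a
1-D search per bin (so the null is exactly nested at sigma2_b = 0 and the
LRT is non-negative by construction); ``mode="full"`` re-optimizes both
ratios jointly per bin. Because the haplotype variance sits on the boundary
under the null, significance is calibrated by phenotype permutation rather
than an asymptotic chi-square reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from mpqtl.binning import BinMap
from mpqtl.io_formats import UNKNOWN

__all__ = ["HQtl", "hgwas_scan", "permutation_threshold", "merge_hqtl", "bin_design"]


@dataclass
class HQtl:
    """A merged bin-haplotype QTL."""

    trait: str
    chrom: str
    start_bp: int
    end_bp: int
    peak_bin: int  # index into the BinMap
    peak_lrt: float
    member_bins: list[int]
    pve: float | None = None


def bin_design(states: np.ndarray, min_state_n: int = 3) -> np.ndarray:
    """Founder-state dummy matrix for one bin.

    States observed in fewer than ``min_state_n`` lines are pooled into a
    single "other" column to stabilize the haplotype variance component;
    UNKNOWN lines get an all-zero row. Returns an (N, m) matrix, empty when
    fewer than two effective states segregate.
    """
    vals, counts = np.unique(states[states != UNKNOWN], return_counts=True)
    common = vals[counts >= min_state_n]
    rare = vals[counts < min_state_n]
    cols = [(states == v).astype(float) for v in common]
    if len(rare) > 0:
        pooled = np.isin(states, rare).astype(float)
        if pooled.sum() > 0:
            cols.append(pooled)
    if len(cols) < 2:
        return np.zeros((len(states), 0))
    return np.column_stack(cols)


class RemlScanner:
    """REML machinery on the eigenbasis of a kinship matrix.

    Caches the rotations of the fixed effects and phenotype so that bin
    scans and permutation scans reuse the expensive eigendecomposition.
    """

    def __init__(self, kinship: np.ndarray, phenotype, pcs: np.ndarray | None):
        y = np.asarray(phenotype, dtype=float)
        n = len(y)
        lam, U = np.linalg.eigh(np.asarray(kinship, dtype=float))
        if lam.min() < -1e-8:
            raise ValueError(f"kinship not PSD: smallest eigenvalue {lam.min():.3e}")
        self.lam = np.maximum(lam, 0.0)
        self.Ut = U.T
        self.X = np.ones((n, 1)) if pcs is None else np.column_stack((np.ones(n), pcs))
        self.n, self.p = n, self.X.shape[1]
        self.Xr = self.Ut @ self.X
        self.set_phenotype(y)

    def set_phenotype(self, y) -> None:
        self.y = np.asarray(y, dtype=float)
        self.yr = self.Ut @ self.y
        self._null = None

    # -- two-component (null) likelihood -----------------------------------

    def _null_ll(self, gamma_g: float) -> float:
        d = gamma_g * self.lam + 1.0
        yd, Xd = self.yr / d, self.Xr / d[:, None]
        XtHX = self.Xr.T @ Xd
        XtHy = Xd.T @ self.yr
        try:
            beta = np.linalg.solve(XtHX, XtHy)
        except np.linalg.LinAlgError:
            return -1e30
        ypy = float(self.yr @ yd - XtHy @ beta)
        sign, ld_x = np.linalg.slogdet(XtHX)
        if sign <= 0 or ypy <= 0:
            return -1e30
        n, p = self.n, self.p
        return -0.5 * ((n - p) * np.log(ypy / (n - p)) + np.log(d).sum() + ld_x)

    def fit_null(self) -> tuple[float, float]:
        """Restricted logL and polygenic ratio gamma_g maximizing it."""
        if self._null is not None:
            return self._null

        def nll(lg):
            return -self._null_ll(np.exp(lg))

        grid = np.linspace(-8, 8, 33)
        i = int(np.argmin([nll(g) for g in grid]))
        res = optimize.minimize_scalar(
            nll, bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
            method="bounded", options={"xatol": 1e-6},
        )
        self._null = (-res.fun, float(np.exp(res.x)))
        return self._null

    # -- three-component likelihood ----------------------------------------

    def _bin_stats(self, Zr: np.ndarray, gamma_g: float) -> dict:
        """Projections of one bin's rotated design, at a fixed gamma_g."""
        d = gamma_g * self.lam + 1.0
        Zd = Zr / d[:, None]
        yd, Xd = self.yr / d, self.Xr / d[:, None]
        return {
            "logdet_d": np.log(d).sum(),
            "ZtDZ": Zr.T @ Zd, "ZtDy": Zd.T @ self.yr, "ZtDX": Zd.T @ self.Xr,
            "ytDy": float(self.yr @ yd), "XtDX": self.Xr.T @ Xd,
            "XtDy": Xd.T @ self.yr,
        }

    def _full_ll_from_stats(self, st: dict, gamma_b: float) -> float:
        m = st["ZtDZ"].shape[0]
        n, p = self.n, self.p
        if gamma_b <= 0:
            XtHX, XtHy = st["XtDX"], st["XtDy"]
            ypy_part = st["ytDy"]
            logdet = st["logdet_d"]
        else:
            Cap = st["ZtDZ"] + np.eye(m) / gamma_b
            try:
                Cf = np.linalg.cholesky(Cap)
            except np.linalg.LinAlgError:
                return -1e30
            logdet = st["logdet_d"] + 2 * np.log(np.diag(Cf)).sum() + m * np.log(gamma_b)
            CiZy = np.linalg.solve(Cap, st["ZtDy"])
            CiZX = np.linalg.solve(Cap, st["ZtDX"])
            XtHX = st["XtDX"] - st["ZtDX"].T @ CiZX
            XtHy = st["XtDy"] - st["ZtDX"].T @ CiZy
            ypy_part = st["ytDy"] - float(st["ZtDy"] @ CiZy)
        try:
            beta = np.linalg.solve(XtHX, XtHy)
        except np.linalg.LinAlgError:
            return -1e30
        ypy = ypy_part - float(XtHy @ beta)
        sign, ld_x = np.linalg.slogdet(XtHX)
        if sign <= 0 or ypy <= 0:
            return -1e30
        return -0.5 * ((n - p) * np.log(ypy / (n - p)) + logdet + ld_x)

    def bin_ll(self, Zr: np.ndarray, gamma_g: float, mode: str = "p3d") -> float:
        """Maximized restricted logL of the full model for one bin.

        ``mode="p3d"`` holds the polygenic ratio at ``gamma_g`` and searches
        the haplotype ratio only; ``mode="full"`` polishes both ratios.
        """
        st = self._bin_stats(Zr, gamma_g)

        def nll_b(lb):
            return -self._full_ll_from_stats(st, np.exp(lb))

        grid = np.linspace(-9, 5, 15)
        i = int(np.argmin([nll_b(g) for g in grid]))
        res = optimize.minimize_scalar(
            nll_b, bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
            method="bounded", options={"xatol": 1e-5},
        )
        ll = -res.fun
        ll = max(ll, self._full_ll_from_stats(st, 0.0))
        if mode == "full":
            def nll2(t):
                st2 = self._bin_stats(Zr, np.exp(t[0]))
                return -self._full_ll_from_stats(st2, np.exp(t[1]))

            start = [np.log(max(gamma_g, 1e-8)), res.x]
            out = optimize.minimize(nll2, start, method="Nelder-Mead",
                                    options={"xatol": 1e-4, "fatol": 1e-8,
                                             "maxiter": 200})
            ll = max(ll, -out.fun)
        return ll


def hgwas_scan(
    bins: BinMap,
    phenotype,
    bin_kinship: np.ndarray,
    pcs: np.ndarray | None = None,
    min_state_n: int = 3,
    mode: str = "p3d",
    scanner: RemlScanner | None = None,
    bin_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Per-bin REML likelihood-ratio statistics.

    Returns LRT values aligned with ``bins.bins`` (or with ``bin_idx`` when
    a subset is requested); bins with a single observed founder state get
    LRT 0. A prebuilt :class:`RemlScanner` can be supplied to reuse the
    kinship eigendecomposition across traits or permutations.
    """
    ws = scanner or RemlScanner(bin_kinship, phenotype, pcs)
    ll0, gg0 = ws.fit_null()
    idx = np.arange(bins.n_bins) if bin_idx is None else np.asarray(bin_idx, int)
    lrt = np.zeros(len(idx))
    for k, b in enumerate(idx):
        Z = bin_design(bins.states[:, b], min_state_n)
        if Z.shape[1] == 0:
            continue
        ll1 = ws.bin_ll(ws.Ut @ Z, gg0, mode=mode)
        lrt[k] = max(0.0, 2.0 * (ll1 - ll0))
    return lrt


def permutation_threshold(
    bins: BinMap,
    phenotype,
    bin_kinship: np.ndarray,
    pcs: np.ndarray | None = None,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
    min_state_n: int = 3,
    mode: str = "p3d",
) -> float:
    """Genome-wide LRT cutoff from phenotype permutations.

    Phenotype values are shuffled across lines ``n_perm`` times; the cutoff
    is the empirical (1 - alpha) quantile of the per-permutation genome-wide
    maximum LRT.
    """
    if n_perm < 20:
        import warnings

        warnings.warn("fewer than 20 permutations: quantile estimate is unstable")
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    ws = RemlScanner(bin_kinship, y, pcs)
    rotated = []
    for b in range(bins.n_bins):
        Z = bin_design(bins.states[:, b], min_state_n)
        if Z.shape[1]:
            rotated.append(ws.Ut @ Z)
    maxes = np.empty(n_perm)
    for it in range(n_perm):
        ws.set_phenotype(rng.permutation(y))
        ll0, gg0 = ws.fit_null()
        best = 0.0
        for Zr in rotated:
            best = max(best, 2.0 * (ws.bin_ll(Zr, gg0, mode=mode) - ll0))
        maxes[it] = max(best, 0.0)
    return float(np.quantile(maxes, 1.0 - alpha))


def merge_hqtl(
    bins: BinMap,
    lrt: np.ndarray,
    cutoff: float,
    max_gap_bp: int = 1_000_000,
    max_gap_bins: int = 5,
    trait: str = "trait",
) -> list[HQtl]:
    """Merge significant bins into hQTL.

    Consecutive significant bins on a chromosome are chained when separated
    by at most ``max_gap_bp`` of physical distance OR at most
    ``max_gap_bins`` intervening bins. The peak is the max-LRT member and
    the interval is delimited by the member bins' physical span.
    """
    lrt = np.asarray(lrt)
    sig = np.flatnonzero(lrt >= cutoff)
    chroms = bins.bins["chrom"].to_numpy(str)
    starts = bins.bins["start_bp"].to_numpy(np.int64)
    ends = bins.bins["end_bp"].to_numpy(np.int64)
    out: list[HQtl] = []
    cluster: list[int] = []

    def flush():
        if not cluster:
            return
        peak = cluster[int(np.argmax(lrt[cluster]))]
        out.append(HQtl(
            trait=trait, chrom=chroms[cluster[0]],
            start_bp=int(starts[cluster[0]]), end_bp=int(ends[cluster[-1]]),
            peak_bin=int(peak), peak_lrt=float(lrt[peak]),
            member_bins=list(cluster),
        ))
        cluster.clear()

    for b in sig:
        if cluster:
            prev = cluster[-1]
            same = chroms[b] == chroms[prev]
            near = (starts[b] - ends[prev] <= max_gap_bp) or (b - prev - 1 <= max_gap_bins)
            if not (same and near):
                flush()
        cluster.append(int(b))
    flush()
    return out
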