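"""Multi-environment BLUP, variance components, heritability and PVE.

The phenotyping model is ``y_ie = mu + line_i + env_e + eps_ie`` with line
and environment random. REML estimates of the three variance components are
obtained by direct maximization of the restricted likelihood using the
Woodbury identity on the random-effect design (no external mixed-model
engine), and line values are the shrunken predictors ``mu + BLUP_i``.
Line-mean broad-sense heritability over n environments is
``H2 = sigma2_g / (sigma2_g + sigma2_e / n)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from mpqtl.io_formats import UNKNOWN, PhenotypeTable

logger = logging.getLogger("mpqtl")

__all__ = ["VarianceComponents", "fit_blup", "heritability", "qtl_pve"]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    n_env: int
    sigma2_env: float = 0.0


def _reml_nll(theta, y, X, Z, M, q_line, q_env):
    """Negative restricted log-likelihood of the two-way random model."""
    try:
        return _reml_nll_inner(theta, y, X, Z, M, q_line, q_env)
    except np.linalg.LinAlgError:
        return 1e30


def _reml_nll_inner(theta, y, X, Z, M, q_line, q_env):
    if np.any(np.abs(theta) > 60):
        return 1e30
    s_l, s_v, s_e = np.exp(theta)
    n, p = X.shape
    d = np.concatenate((np.full(q_line, s_l), np.full(q_env, s_v)))
    # V = Z diag(d) Z' + s_e I ; capacitance C = s_e diag(1/d) + Z'Z
    C = M + np.diag(s_e / d)
    try:
        Cf = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return 1e30
    # det V = s_e^(n-q) * prod(d) * det(C) with q = q_line + q_env
    logdet_V = (n - q_line - q_env) * np.log(s_e) \
        + 2 * np.log(np.diag(Cf)).sum() + np.log(d).sum()
    def vinv(B):
        ZtB = Z.T @ B
        return (B - Z @ np.linalg.solve(C, ZtB)) / s_e

    ViX = vinv(X)
    Viy = vinv(y)
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return 1e30
    yPy = float(y @ Viy - XtViy @ beta)
    sign, logdet_XVX = np.linalg.slogdet(XtViX)
    if sign <= 0 or yPy <= 0 or not np.isfinite(yPy):
        return 1e30
    return 0.5 * (logdet_V + logdet_XVX + yPy)


def fit_blup(pheno: PhenotypeTable, trait: str):
    """REML fit of the line x environment model; returns (BLUPs, components).

    The returned series holds ``mu + BLUP_i`` per line. With a single
    environment the variance components are not separable: the line means
    are returned unchanged with a warning and degenerate components.
    """
    sub = pheno.table[pheno.table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} absent from phenotype table")
    lines = sorted(sub["line"].unique())
    envs = sorted(sub["env"].unique())
    if len(envs) < 2:
        warnings.warn("single environment: returning line means, components degenerate")
        means = sub.groupby("line")["value"].mean().reindex(lines)
        return means, VarianceComponents(np.nan, np.nan, 1)

    li = {l: i for i, l in enumerate(lines)}
    ei = {e: i for i, e in enumerate(envs)}
    y = sub["value"].to_numpy(float)
    n = len(y)
    q1, q2 = len(lines), len(envs)
    Z = np.zeros((n, q1 + q2))
    Z[np.arange(n), [li[l] for l in sub["line"]]] = 1.0
    Z[np.arange(n), [q1 + ei[e] for e in sub["env"]]] = 1.0
    X = np.ones((n, 1))
    M = Z.T @ Z

    v0 = max(y.var(), 1e-8)
    x0 = np.log([v0 / 2, v0 / 4, v0 / 2])
    res = optimize.minimize(
        _reml_nll, x0, args=(y, X, Z, M, q1, q2), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    s_l, s_v, s_e = np.exp(res.x)

    d = np.concatenate((np.full(q1, s_l), np.full(q2, s_v)))
    C = M + np.diag(s_e / d)

    def vinv(B):
        return (B - Z @ np.linalg.solve(C, Z.T @ B)) / s_e

    ViX, Viy = vinv(X), vinv(y)
    beta = float((X[:, 0] @ Viy) / (X[:, 0] @ ViX[:, 0]))
    r = y - beta
    u = d * (Z.T @ vinv(r))
    blups = pd.Series(beta + u[:q1], index=lines, name=trait)
    vc = VarianceComponents(float(s_l), float(s_e), len(envs), sigma2_env=float(s_v))
    return blups, vc


def heritability(vc: VarianceComponents) -> float:
    """Line-mean broad-sense heritability sigma2_g / (sigma2_g + sigma2_e/n)."""
    if vc.n_env <= 0:
        raise ValueError("n_env must be positive")
    denom = vc.sigma2_g + vc.sigma2_e / vc.n_env
    if denom == 0:
        raise ValueError("both variance components are zero")
    return vc.sigma2_g / denom


def _design_columns(predictor) -> np.ndarray:
    """Numeric design for one QTL predictor.

    ``("dosage", x)`` uses the dosage vector as a single column;
    ``("states", s)`` one-hot encodes founder states with the most frequent
    state as reference (UNKNOWN rows get all-zero indicators).
    """
    kind, x = predictor
    x = np.asarray(x)
    if kind == "dosage":
        return x.astype(float)[:, None]
    if kind == "states":
        vals, counts = np.unique(x[x != UNKNOWN], return_counts=True)
        ref = vals[np.argmax(counts)]
        cols = [(x == v).astype(float) for v in vals if v != ref]
        return np.column_stack(cols) if cols else np.zeros((len(x), 0))
    raise ValueError(f"unknown predictor kind {kind!r}")


def _r2(y: np.ndarray, cols: np.ndarray) -> float:
    y = y - y.mean()
    if cols.shape[1] == 0:
        return 0.0
    Xc = cols - cols.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        logger.warning("dropping %d collinear predictor columns", Xc.shape[1] - rank)
    coef, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    fitted = Xc @ coef
    tss = float(y @ y)
    return float(fitted @ fitted) / tss if tss > 0 else 0.0


def qtl_pve(phenotype, predictors: list) -> tuple[list[float], float]:
    """Per-QTL and joint proportion of phenotypic variance explained.

    Each predictor is ``("dosage", vector)`` for a peak-SNP dosage or
    ``("states", vector)`` for a peak-bin founder-state factor. Per-QTL PVE
    is the R-squared of the single-predictor regression on the line values;
    joint PVE is the R-squared of the multiple regression on all of them.
    """
    y = np.asarray(phenotype, dtype=float)
    singles = [_r2(y, _design_columns(p)) for p in predictors]
    if predictors:
        joint = _r2(y, np.column_stack([_design_columns(p) for p in predictors]))
    else:
        joint = 0.0
    return singles, joint
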