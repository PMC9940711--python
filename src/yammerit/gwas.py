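"""Marker-trait association with a K+Q mixed linear model.

The scan follows the EMMA-class exact strategy: eigendecompose the
VanRaden kinship once, estimate the residual-to-genetic variance ratio
delta by REML under the null model (intercept + structure PCs), then
test every marker by generalized least squares in the rotated space
where the covariance is diagonal. The variance ratio is held at its
null value across markers (the population-parameters-previously-
determined shortcut); exact per-marker REML is available behind a flag.
A naive per-marker regression (no kinship, no structure) is provided
for comparison, along with the Bonferroni-style LOD threshold
-log10(alpha / n_markers).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, allele_frequencies
from .mixed import KinshipEigen, _reml_neg_loglik, fit_reml_kinship
from .structure import pca_genotypes

log = logging.getLogger(__name__)


def vanraden_kinship(geno: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Centered cross-product genomic relationship matrix.

    K = M M' / (2 sum_m p_m (1 - p_m)) with M the dosage matrix centered
    at twice the allele frequency. Monomorphic markers contribute
    nothing to the numerator and are excluded from the denominator.
    """
    x = geno.dosage.astype(float) if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    if x.size == 0:
        raise ValueError("empty genotype matrix")
    if np.any(x < 0):
        raise ValueError("vanraden_kinship requires an imputed matrix")
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    M = x[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    if denom <= 0:
        raise ValueError("no polymorphic markers")
    return (M @ M.T) / denom


def _batched_gls_scan(
    y: np.ndarray, X0: np.ndarray, G: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker GLS t-tests of y on [X0, g] with diagonal covariance.

    ``weights`` are the covariance diagonal entries; all arrays already
    live in the rotated space. Returns (effects, p_values, ok_mask).
    """
    sw = 1.0 / np.sqrt(weights)
    yw = y * sw
    X0w = X0 * sw[:, None]
    Gw = G * sw[:, None]
    n, p0 = X0w.shape

    A = X0w.T @ X0w
    Ainv = np.linalg.inv(A)
    beta0 = Ainv @ (X0w.T @ yw)
    resid0 = yw - X0w @ beta0
    rss0 = float(resid0 @ resid0)

    Gt = Gw - X0w @ (Ainv @ (X0w.T @ Gw))  # markers projected off covariates
    gg = np.einsum("ij,ij->j", Gt, Gt)
    gy = Gt.T @ resid0
    ok = gg > 1e-10 * n
    df = n - p0 - 1
    effect = np.zeros(G.shape[1])
    pval = np.ones(G.shape[1])
    effect[ok] = gy[ok] / gg[ok]
    rss = rss0 - gy[ok] ** 2 / gg[ok]
    sigma2 = np.clip(rss, 1e-300, None) / df
    se = np.sqrt(sigma2 / gg[ok])
    tstat = effect[ok] / se
    pval[ok] = 2.0 * stats.t.sf(np.abs(tstat), df)
    return effect, np.clip(pval, np.finfo(float).tiny, 1.0), ok


def _records(geno: GenotypeMatrix, effect, pval, ok, y) -> pd.DataFrame:
    maf = np.fmin(allele_frequencies(geno), 1 - allele_frequencies(geno))
    x = geno.dosage.astype(float)
    yv = np.asarray(y, float)
    with np.errstate(invalid="ignore"):
        sd = x.std(axis=0)
        r = np.where(sd > 0, ((x - x.mean(0)) * (yv - yv.mean())[:, None]).mean(0)
                     / np.where(sd == 0, 1, sd) / yv.std(), 0.0)
    return pd.DataFrame(
        {
            "marker_id": geno.panel.marker_id,
            "chromosome": geno.panel.chromosome,
            "position": geno.panel.position,
            "p_value": pval,
            "effect": effect,
            "MAF": maf,
            "LOD": -np.log10(pval),
            "R2_marginal_pct": 100.0 * r**2,
            "tested": ok,
        }
    )


def mlm_scan(
    blues: np.ndarray | pd.Series,
    geno: GenotypeMatrix,
    K: np.ndarray | None = None,
    n_pcs: int = 3,
    per_marker_reml: bool = False,
) -> pd.DataFrame:
    """K+Q mixed-model association scan.

    ``blues``: genotype-mean phenotypes aligned with ``geno`` samples.
    Structure covariates are the leading ``n_pcs`` genotype principal
    components (0 disables them). Returns one record per marker with
    p-value, additive effect, MAF, and LOD = -log10(p).
    """
    y = np.asarray(blues, float).ravel()
    if len(y) != geno.n_samples:
        raise ValueError("phenotype length must match sample count")
    if K is None:
        K = vanraden_kinship(geno)
    eigen = KinshipEigen.from_kinship(K)
    X0 = np.ones((len(y), 1))
    if n_pcs > 0:
        scores, _, _ = pca_genotypes(geno, n_components=n_pcs)
        X0 = np.hstack([X0, scores])
    fit = fit_reml_kinship(y, X0, eigen)
    yr = eigen.U.T @ y
    X0r = eigen.U.T @ X0
    Gr = eigen.U.T @ geno.dosage.astype(float)
    if not per_marker_reml:
        w = eigen.S + fit.delta
        effect, pval, ok = _batched_gls_scan(yr, X0r, Gr, w)
    else:
        m = geno.n_markers
        effect = np.zeros(m)
        pval = np.ones(m)
        ok = np.zeros(m, bool)
        for j in range(m):
            Xj = np.hstack([X0, geno.dosage[:, [j]].astype(float)])
            grid = np.arange(-10.0, 10.0 + 1e-9, 0.5)
            Xjr = eigen.U.T @ Xj
            best = min(grid, key=lambda g: _reml_neg_loglik(g, yr, Xjr, eigen.S))
            w = eigen.S + np.exp(best)
            e_j, p_j, ok_j = _batched_gls_scan(yr, X0r, Gr[:, [j]], w)
            effect[j], pval[j], ok[j] = e_j[0], p_j[0], ok_j[0]
    return _records(geno, effect, pval, ok, y)


def naive_scan(blues: np.ndarray | pd.Series, geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker simple linear regression (no kinship, no structure)."""
    y = np.asarray(blues, float).ravel()
    if len(y) != geno.n_samples:
        raise ValueError("phenotype length must match sample count")
    X0 = np.ones((len(y), 1))
    G = geno.dosage.astype(float)
    effect, pval, ok = _batched_gls_scan(y, X0, G, np.ones(len(y)))
    return _records(geno, effect, pval, ok, y)


def significance_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Bonferroni-style LOD threshold -log10(alpha / n_markers)."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return float(-np.log10(alpha / n_markers))


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic control lambda: median association chi-square / 0.4549."""
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def significant_snp_effects(
    blues: np.ndarray | pd.Series, geno: GenotypeMatrix, significant_ids
) -> pd.DataFrame:
    """Joint multiple-regression effects and incremental R2 of chosen SNPs.

    The trait is regressed on all significant SNPs together; each SNP's
    effect is its partial coefficient. R2 (%) is the incremental
    (type-I) sum of squares attributed in order of marginal p-value.
    Collinear SNPs are dropped with a flag.
    """
    y = np.asarray(blues, float).ravel()
    ids = list(significant_ids)
    if len(ids) == 0:
        raise ValueError("need at least one significant SNP")
    panel_ids = list(geno.panel.marker_id)
    idx = [panel_ids.index(s) for s in ids]
    G = geno.dosage[:, idx].astype(float)

    # marginal p-values fix the attribution order
    _, pvals, _ = _batched_gls_scan(y, np.ones((len(y), 1)), G, np.ones(len(y)))
    order = np.argsort(pvals)

    tss = float(((y - y.mean()) ** 2).sum())
    X = np.ones((len(y), 1))
    rss_prev = tss
    rows = []
    kept_cols = []
    for rank, j in enumerate(order):
        Xc = np.hstack([X, G[:, [j]]])
        if np.linalg.matrix_rank(Xc) <= X.shape[1]:
            rows.append({"marker_id": ids[j], "p_marginal": pvals[j], "effect": np.nan,
                         "R2_pct": 0.0, "dropped_collinear": True})
            continue
        beta, rss_arr, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        resid = y - Xc @ beta
        rss = float(resid @ resid)
        rows.append({"marker_id": ids[j], "p_marginal": pvals[j], "effect": np.nan,
                     "R2_pct": 100.0 * (rss_prev - rss) / tss, "dropped_collinear": False})
        X = Xc
        kept_cols.append(j)
        rss_prev = rss
    # joint partial coefficients for the kept SNPs
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coef_by_col = dict(zip(kept_cols, beta[1:]))
    out = pd.DataFrame(rows)
    for j, coef in coef_by_col.items():
        out.loc[out["marker_id"] == ids[j], "effect"] = coef
    out["LOD_marginal"] = -np.log10(out["p_marginal"])
    return out
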