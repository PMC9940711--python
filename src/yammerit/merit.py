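"""Multi-trait genetic merit: genomic values, factor analysis, FAI-BLUP.

The merit workflow ranks genotypes by proximity, in varimax-rotated
factor-score space, to an ideotype whose coordinates are the
desirability-aligned extremes of the observed scores. Working in
rotated factor space frees the index from multicollinearity among
traits; a lower index (distance) is better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed import gblup

log = logging.getLogger(__name__)


def genomic_genetic_values(blues: pd.DataFrame, K: np.ndarray) -> pd.DataFrame:
    """Per-trait genomic BLUPs of genotype effects.

    Each trait's genotype means are decomposed as mu + u + e with
    u ~ N(0, K sigma_g^2); the REML-shrunken u are returned. A singular
    system gets a 1e-6 ridge on K with a warning.
    """
    n = len(blues)
    if K.shape != (n, n):
        raise ValueError("kinship must align with genotype means")
    X = np.ones((n, 1))
    out = {}
    for t in blues.columns:
        y = blues[t].to_numpy(float)
        try:
            u, _ = gblup(y, X, K)
        except np.linalg.LinAlgError:
            log.warning("singular mixed-model system for %s; adding 1e-6 ridge", t)
            u, _ = gblup(y, X, K + 1e-6 * np.eye(n))
        out[t] = u
    return pd.DataFrame(out, index=blues.index)


def _varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Orthogonal varimax rotation matrix for a loading matrix."""
    p, k = loadings.shape
    if k < 2:
        return np.eye(k)
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - (L @ np.diag((L**2).sum(axis=0))) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return R


@dataclass
class FactorModel:
    """Exploratory factor model of the genetic-value correlation matrix."""

    traits: list
    corr: pd.DataFrame
    eigenvalues: np.ndarray
    n_retained: int
    loadings_raw: pd.DataFrame  # traits x factors, before rotation
    loadings: pd.DataFrame  # varimax-rotated
    communalities: pd.Series
    scores: pd.DataFrame  # genotypes x factors (regression method)
    explained_pct: float  # % of total trait variance in retained factors


def factor_analysis(
    genetic_values: pd.DataFrame, retain_rule: str = "eigen_gt_1", standardize: bool = True
) -> FactorModel:
    """Principal-component factor extraction with varimax rotation.

    Factors with eigenvalue > 1 of the trait correlation matrix are
    retained (at least one); loadings are eigenvectors scaled by the
    root eigenvalue, rotated by varimax; scores use the regression
    method Z R^{-1} Lambda. Deterministic sign convention: each factor's
    largest-magnitude loading is positive.
    """
    traits = list(genetic_values.columns)
    if len(traits) < 3:
        raise ValueError("need >= 3 traits")
    if len(genetic_values) <= len(traits):
        raise ValueError("need more genotypes than traits")
    Z = genetic_values.to_numpy(float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1) if standardize else Z.copy()
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    if evals.min() < -1e-10:
        log.warning("correlation matrix not PSD; clipping negative eigenvalues")
        evals = np.clip(evals, 1e-10, None)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    if retain_rule == "eigen_gt_1":
        k = max(int((evals > 1.0).sum()), 1)
    elif isinstance(retain_rule, int):
        k = retain_rule
    else:
        raise ValueError(f"unknown retain rule {retain_rule!r}")

    L_raw = evecs[:, :k] * np.sqrt(evals[:k])
    rot = _varimax(L_raw)
    L = L_raw @ rot
    flip = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    L = L * flip
    communal = (L**2).sum(axis=1)
    Rinv = np.linalg.pinv(R)
    scores = Z @ Rinv @ L

    cols = [f"FA{i + 1}" for i in range(k)]
    return FactorModel(
        traits=traits,
        corr=pd.DataFrame(R, index=traits, columns=traits),
        eigenvalues=evals,
        n_retained=k,
        loadings_raw=pd.DataFrame(L_raw, index=traits, columns=cols),
        loadings=pd.DataFrame(L, index=traits, columns=cols),
        communalities=pd.Series(communal, index=traits),
        scores=pd.DataFrame(scores, index=genetic_values.index, columns=cols),
        explained_pct=100.0 * evals[:k].sum() / len(traits),
    )


def fai_blup(
    fm: FactorModel,
    desirability: dict,
    select_threshold: float | None = None,
    select_n: int | None = None,
    as_probability: bool = False,
) -> pd.DataFrame:
    """Ideotype-distance merit index over rotated factor scores.

    The ideotype takes, on each rotated factor, the extreme of the
    observed scores in the direction favored by the desirability-
    weighted loadings of that factor. The index is the Euclidean
    distance to the ideotype (lower = better); per-factor contribution
    fractions are the squared distance components. ``as_probability``
    instead reports normalized 1/distance (higher = better).
    """
    missing = set(fm.traits) - set(desirability)
    if missing:
        raise ValueError(f"desirability missing for traits: {sorted(missing)}")
    dropped = fm.scores.index[fm.scores.isna().any(axis=1)]
    scores = fm.scores.drop(index=dropped)
    if len(dropped):
        log.warning("excluded %d genotypes with missing scores", len(dropped))
    d_vec = np.array([desirability[t] for t in fm.traits], float)
    align = fm.loadings.to_numpy().T @ d_vec  # per-factor desirability alignment
    sign = np.where(align >= 0, 1.0, -1.0)
    S = scores.to_numpy()
    ideotype = np.where(sign > 0, S.max(axis=0), S.min(axis=0))

    diff2 = (S - ideotype) ** 2
    fai = np.sqrt(diff2.sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(fai[:, None] > 0, diff2 / np.clip(fai[:, None] ** 2, 1e-300, None),
                           1.0 / fm.n_retained)
    out = pd.DataFrame(index=scores.index)
    out["FAI"] = fai
    if as_probability:
        inv = 1.0 / np.clip(fai, 1e-12, None)
        out["merit_probability"] = inv / inv.sum()
    for i, c in enumerate(fm.scores.columns):
        out[f"contrib_{c}"] = contrib[:, i]
    out["rank"] = out["FAI"].rank(method="first").astype(int)
    if select_n is not None:
        out["selected"] = out["rank"] <= select_n
    elif select_threshold is not None:
        out["selected"] = out["FAI"] < select_threshold
    else:
        out["selected"] = False
    out.attrs["ideotype"] = ideotype
    out.attrs["factor_sign"] = sign
    return out.sort_values("rank")


def selection_gain(
    genetic_values: pd.DataFrame, selected, desirability: dict | None = None
) -> pd.DataFrame:
    """Per-trait gain of the selected set over the population mean."""
    selected = list(selected)
    if len(selected) == 0:
        raise ValueError("empty selection")
    pop_mean = genetic_values.mean(axis=0)
    sel_mean = genetic_values.loc[selected].mean(axis=0)
    gain = sel_mean - pop_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(np.abs(pop_mean) > 1e-12, 100.0 * gain / np.abs(pop_mean), np.nan)
    out = pd.DataFrame({"gain": gain, "gain_pct_of_mean": pct})
    if desirability is not None:
        out["desired_direction"] = [
            np.sign(gain[t]) == np.sign(desirability.get(t, 0)) or gain[t] == 0
            for t in genetic_values.columns
        ]
    return out
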