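"""Genomic prediction of cross performance (GPCP).

Marker additive and dominance effects are estimated with a two-kernel
ridge mixed model (additive design: dosage - 1; dominance design:
heterozygote indicator), variance components by REML, and back-solved
to marker space. The expected F1 mean of a cross follows the Falconer
population-mean algebra per marker:

    M_F1 = a (p - q - y) + d [2 p q + y (p - q)]

with p the alternate-allele gamete frequency of parent 1 (dosage / 2),
q = 1 - p, and y = p - p' the gamete-frequency difference between
parents. This is identical to the genotype-frequency enumeration
M = a (p p' - q q') + d (p q' + p' q), which serves as the independent
oracle in tests. Dioecy gates the enumeration: only female x male
pairs among flowering parents are predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .containers import GenotypeMatrix
from .simulate import DESIRABILITY

log = logging.getLogger(__name__)


@dataclass
class CrossEffects:
    """Per-trait marker effects for cross prediction."""

    marker_id: np.ndarray
    intercept: dict = field(default_factory=dict)  # trait -> mu
    additive: dict = field(default_factory=dict)  # trait -> a (m,)
    dominance: dict = field(default_factory=dict)  # trait -> d (m,)
    variance_components: dict = field(default_factory=dict)
    dominance_at_boundary: dict = field(default_factory=dict)


def _reml_two_kernel(y: np.ndarray, Ka: np.ndarray, Kd: np.ndarray):
    """REML variance components (va, vd, ve) for y = mu + ua + ud + e."""
    n = len(y)
    X = np.ones((n, 1))
    vy = float(np.var(y, ddof=1))
    if vy <= 0:
        return 0.0, 0.0, max(vy, 1e-12)

    def neg_restricted_ll(theta):
        va, vd, ve = np.exp(theta)
        V = va * Ka + vd * Kd + ve * np.eye(n)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        quad = float(r @ np.linalg.solve(V, r))
        s, logdet_x = np.linalg.slogdet(XtViX)
        if s <= 0:
            return np.inf
        return 0.5 * (logdetV + logdet_x + quad)

    x0 = np.log([vy / 3, vy / 6, vy / 2])
    res = minimize(neg_restricted_ll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    va, vd, ve = np.exp(res.x)
    return float(va), float(vd), float(ve)


def estimate_ad_effects(blues: pd.DataFrame, geno: GenotypeMatrix) -> CrossEffects:
    """Two-kernel ridge estimates of per-marker additive/dominance effects.

    The mixed model uses the orthogonal parametrization (breeding
    values + dominance deviations): additive design x - 2p and
    dominance design {-2p^2, 2pq, -2q^2} for dosages {0, 1, 2}. Under
    near-HWE genotype frequencies the two kernels are close to
    orthogonal, which keeps the variance split identifiable even on a
    low-MAF marker spectrum. Per-marker substitution effects alpha and
    dominance deviations delta are back-solved from the kernel BLUP and
    converted to genotypic effects via d = delta and
    a = alpha - d (1 - 2p). A dominance variance at the zero boundary
    sets all d to 0 with a flag.
    """
    x = geno.dosage.astype(float)
    if np.any(x < 0):
        raise ValueError("estimate_ad_effects requires an imputed matrix")
    n, m = x.shape
    p = x.mean(axis=0) / 2.0
    q = 1.0 - p
    Za = x - 2.0 * p
    Zd = np.select(
        [x == 0.0, x == 1.0], [np.broadcast_to(-2.0 * p**2, x.shape),
                               np.broadcast_to(2.0 * p * q, x.shape)],
        default=np.broadcast_to(-2.0 * q**2, x.shape),
    )
    ca = max(np.trace(Za @ Za.T) / n, 1e-12)
    cd = max(np.trace(Zd @ Zd.T) / n, 1e-12)
    Ka = (Za @ Za.T) / ca
    Kd = (Zd @ Zd.T) / cd

    effects = CrossEffects(marker_id=np.asarray(geno.panel.marker_id))
    for t in blues.columns:
        y = blues[t].to_numpy(float)
        va, vd, ve = _reml_two_kernel(y, Ka, Kd)
        total = va + vd + ve
        boundary = vd < 1e-4 * total
        V = va * Ka + vd * Kd + ve * np.eye(n)
        Vi = np.linalg.inv(V)
        ones = np.ones(n)
        mu = float((ones @ Vi @ y) / (ones @ Vi @ ones))
        r = Vi @ (y - mu)
        alpha = (va / ca) * (Za.T @ r)
        delta = np.zeros(m) if boundary else (vd / cd) * (Zd.T @ r)
        if boundary:
            log.info("trait %s: dominance variance at boundary; d set to 0", t)
        d_hat = delta
        a_hat = alpha - d_hat * (1.0 - 2.0 * p)
        effects.intercept[t] = mu
        effects.additive[t] = a_hat
        effects.dominance[t] = d_hat
        effects.variance_components[t] = {"va": va, "vd": vd, "ve": ve}
        effects.dominance_at_boundary[t] = bool(boundary)
    return effects


def falconer_cross_mean(
    dos1: np.ndarray, dos2: np.ndarray, a: np.ndarray, d: np.ndarray,
    strict_compat: bool = False,
) -> float:
    """Summed per-marker Falconer F1 mean for one parent pair (no intercept).

    ``strict_compat`` switches the dominance term to the printed-form
    y(q - p) variant instead of the algebraically consistent y(p - q).
    """
    dos1 = np.asarray(dos1, float)
    dos2 = np.asarray(dos2, float)
    if np.any(dos1 < 0) or np.any(dos2 < 0):
        bad = np.where((dos1 < 0) | (dos2 < 0))[0][0]
        raise ValueError(f"missing parental genotype at effect marker index {bad}")
    p = dos1 / 2.0
    q = 1.0 - p
    y = p - dos2 / 2.0
    dom_sign = -1.0 if strict_compat else 1.0
    per_marker = a * (p - q - y) + d * (2.0 * p * q + dom_sign * y * (p - q))
    return float(per_marker.sum())


def predict_cross_mean(
    dos1: np.ndarray, dos2: np.ndarray, effects: CrossEffects, strict_compat: bool = False
) -> dict:
    """Per-trait predicted F1 mean (intercept + Falconer marker sum)."""
    return {
        t: effects.intercept[t]
        + falconer_cross_mean(dos1, dos2, effects.additive[t], effects.dominance[t], strict_compat)
        for t in effects.intercept
    }


def enumerate_crosses(metadata: pd.DataFrame) -> pd.DataFrame:
    """All female x male pairs among flowering parents.

    Non-flowering samples never enter; same-sex and self pairs are
    impossible by construction. Zero females or zero males yields an
    empty frame with a warning.
    """
    flowering = metadata[metadata["flowering"].astype(bool)]
    females = flowering.loc[flowering["sex"] == "female", "id"].to_numpy()
    males = flowering.loc[flowering["sex"] == "male", "id"].to_numpy()
    if len(females) == 0 or len(males) == 0:
        log.warning("no %s parents; cross list empty", "female" if len(females) == 0 else "male")
        return pd.DataFrame(columns=["female", "male"])
    return pd.DataFrame(
        {"female": np.repeat(females, len(males)), "male": np.tile(males, len(females))}
    )


def predict_all_crosses(
    geno: GenotypeMatrix, effects: CrossEffects, crosses: pd.DataFrame,
    strict_compat: bool = False,
) -> pd.DataFrame:
    """Vectorized per-trait F1 means for every enumerated cross."""
    ids = list(geno.sample_ids)
    fi = np.array([ids.index(s) for s in crosses["female"]])
    mi = np.array([ids.index(s) for s in crosses["male"]])
    x = geno.dosage.astype(float)
    p1 = x[fi] / 2.0  # pairs x markers
    p2 = x[mi] / 2.0
    q1 = 1.0 - p1
    y = p1 - p2
    dom_sign = -1.0 if strict_compat else 1.0
    out = crosses.copy()
    for t in effects.intercept:
        a, d = effects.additive[t], effects.dominance[t]
        add = (p1 - q1 - y) @ a
        dom = (2.0 * p1 * q1 + dom_sign * y * (p1 - q1)) @ d
        out[t] = effects.intercept[t] + add + dom
    return out


def crossing_merit_summary(
    predictions: pd.DataFrame, weights: dict | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Total cross merit and parent-level compatibility summary.

    Total merit per cross = sum over traits of weight * z-scored
    predicted F1 mean (weights default to the trait desirability signs,
    equal magnitude). Per parent: mean merit over its crosses, net
    merit sign, and the count of partners giving a positive-merit cross
    ("crossing compatibility").
    """
    if len(predictions) == 0:
        raise ValueError("no predictions")
    traits = [c for c in predictions.columns if c not in ("female", "male")]
    if weights is None:
        weights = {t: float(DESIRABILITY.get(t, 1)) for t in traits}
    preds = predictions.copy()
    merit = np.zeros(len(preds))
    for t in traits:
        v = preds[t].to_numpy(float)
        sd = v.std(ddof=0)
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        merit += weights.get(t, 0.0) * z
    preds["total_merit"] = merit

    rows = []
    for col, role in (("female", "female"), ("male", "male")):
        for parent, grp in preds.groupby(col):
            rows.append(
                {
                    "parent": parent,
                    "role": role,
                    "n_crosses": len(grp),
                    "mean_merit": grp["total_merit"].mean(),
                    "net_merit_positive": grp["total_merit"].mean() > 0,
                    "compatibility": int((grp["total_merit"] > 0).sum()),
                }
            )
    parent_summary = pd.DataFrame(rows).sort_values("mean_merit", ascending=False)
    return preds, parent_summary.reset_index(drop=True)
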