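"""Population structure and differentiation.

Implements the structure workflow a diversity panel goes through:
principal components on the dosage matrix, k-means with a BIC curve to
pick the number of clusters, a binomial admixture model maximized by
EM (ancestry proportions Q and cluster allele frequencies F), genetic
distance matrices (1 - IBS and Jaccard), Ward hierarchical clustering
with Newick export, AMOVA from squared pairwise distances, and the
Weir--Cockerham two-population Fst estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .containers import GenotypeMatrix

log = logging.getLogger(__name__)

F_EPS = 1e-6  # cluster allele frequencies clamped to [F_EPS, 1-F_EPS]


# ---------------------------------------------------------------------------
# PCA and BIC-based cluster number selection
# ---------------------------------------------------------------------------

def pca_genotypes(
    geno: GenotypeMatrix | np.ndarray, n_components: int = 10, scale: bool = False
):
    """SVD principal components of the (centered) dosage matrix.

    Returns ``(scores, loadings, explained_variance)``. Sign convention:
    each component is flipped so its largest-magnitude loading is
    positive, making results deterministic.
    """
    X = geno.dosage.astype(float) if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    n, m = X.shape
    if n_components > min(n, m):
        raise ValueError(f"n_components={n_components} exceeds min(n,m)={min(n, m)}")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    flip = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = U * s * flip[None, :]
    loadings = Vt * flip[:, None]
    explained = s**2 / (n - 1)
    return scores, loadings.T, explained


def select_k_bic(scores: np.ndarray, k_range=range(2, 11), seed: int = 0, n_init: int = 10):
    """k-means BIC curve over candidate cluster counts.

    BIC(k) = n ln(WSS_k / n) + k ln(n); the optimum is the argmin. The
    full curve is returned so an elbow can also be read off.
    """
    scores = np.asarray(scores, float)
    n = scores.shape[0]
    bic = {}
    for k in k_range:
        if k >= n:
            log.warning("select_k_bic: skipping k=%d >= n=%d", k, n)
            continue
        if k == 1:
            wss = ((scores - scores.mean(axis=0)) ** 2).sum()
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(scores)
            wss = km.inertia_
        bic[k] = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
    if not bic:
        raise ValueError("no feasible k in k_range")
    k_opt = min(bic, key=bic.get)
    return bic, k_opt


# ---------------------------------------------------------------------------
# Admixture model EM
# ---------------------------------------------------------------------------

@dataclass
class StructureResult:
    """Fitted admixture model."""

    K: int
    Q: np.ndarray  # n x K, rows sum to 1
    F: np.ndarray  # K x m cluster alternate-allele frequencies
    loglik_trace: np.ndarray
    converged: bool
    sample_ids: np.ndarray | None = None
    bic_by_k: dict = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _admixture_loglik(x: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    pi = np.clip(Q @ F, F_EPS, 1 - F_EPS)
    return float(np.sum(x * np.log(pi) + (2 - x) * np.log1p(-pi)))


def admixture_em(
    geno: GenotypeMatrix | np.ndarray,
    K: int,
    tol: float = 1e-5,
    max_iter: int = 2000,
    seed: int = 0,
    init_labels: np.ndarray | None = None,
) -> StructureResult:
    """Maximum-likelihood admixture proportions by EM.

    Maximizes the binomial likelihood of dosages x_im given
    pi_im = sum_k Q_ik F_km via the standard block EM updates of Q and
    F. Initialization softens k-means hard labels (on 10 PCs) to
    0.9 / uniform-rest. Stops when the log-likelihood gain drops below
    ``tol``; non-convergence returns the best iterate with
    ``converged=False`` rather than raising.
    """
    if isinstance(geno, GenotypeMatrix):
        x = geno.dosage.astype(float)
        sample_ids = geno.sample_ids
    else:
        x = np.asarray(geno, float)
        sample_ids = None
    if np.any(x < 0):
        raise ValueError("admixture_em requires an imputed (no-missing) dosage matrix")
    n, m = x.shape
    if K < 1:
        raise ValueError("K must be >= 1")

    if K == 1:
        F = np.clip(x.mean(axis=0, keepdims=True) / 2.0, F_EPS, 1 - F_EPS)
        Q = np.ones((n, 1))
        ll = _admixture_loglik(x, Q, F)
        return StructureResult(K=1, Q=Q, F=F, loglik_trace=np.array([ll]), converged=True,
                               sample_ids=sample_ids)

    if init_labels is None:
        n_pc = min(10, n - 1, m)
        scores, _, _ = pca_genotypes(x, n_components=n_pc)
        init_labels = KMeans(n_clusters=K, n_init=10, random_state=seed).fit_predict(scores)
    Q = np.full((n, K), 0.1 / max(K - 1, 1))
    Q[np.arange(n), init_labels] = 0.9
    Q /= Q.sum(axis=1, keepdims=True)
    # frequency init from soft label averages
    F = np.clip((Q.T @ x) / (2.0 * Q.sum(axis=0)[:, None]), F_EPS, 1 - F_EPS)

    trace = [_admixture_loglik(x, Q, F)]
    converged = False
    for _ in range(max_iter):
        pi = np.clip(Q @ F, F_EPS, 1 - F_EPS)
        r_alt = x / pi  # n x m
        r_ref = (2.0 - x) / (1.0 - pi)
        # expected allele-origin counts
        A = Q * (r_alt @ F.T)  # n x K, alt-allele copies from cluster k
        B = Q * (r_ref @ (1.0 - F).T)  # ref-allele copies
        Q_new = (A + B) / (2.0 * m)
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        # F update (same E-step quantities): expected alt/ref copies per (k, m)
        alt_counts = F * (Q.T @ r_alt)
        ref_counts = (1.0 - F) * (Q.T @ r_ref)
        F_new = np.clip(alt_counts / np.clip(alt_counts + ref_counts, 1e-300, None), F_EPS, 1 - F_EPS)
        Q, F = Q_new, F_new
        ll = _admixture_loglik(x, Q, F)
        trace.append(ll)
        if trace[-1] - trace[-2] < tol:
            converged = True
            break
    if not converged:
        log.warning("admixture_em: no convergence after %d iterations", max_iter)
    return StructureResult(
        K=K, Q=Q, F=F, loglik_trace=np.array(trace), converged=converged, sample_ids=sample_ids
    )


def assign_membership(Q: np.ndarray, threshold: float = 0.70) -> np.ndarray:
    """Hard cluster labels from ancestry proportions.

    A sample whose maximum ancestry fraction reaches the threshold
    (>=, boundary counts as assigned) gets that cluster's 1-based
    label as a string; otherwise ``"admixed"``.
    """
    Q = np.asarray(Q, float)
    best = Q.argmax(axis=1)
    top = Q[np.arange(len(Q)), best]
    return np.where(top >= threshold, (best + 1).astype(str), "admixed")


# ---------------------------------------------------------------------------
# Distances, Ward clustering
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    sample_ids: np.ndarray
    values: np.ndarray  # symmetric, zero diagonal
    method: str

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def distance_matrix(geno: GenotypeMatrix, method: str = "one_minus_ibs") -> DistanceMatrix:
    """Pairwise genetic dissimilarity.

    ``one_minus_ibs``: d_ij = mean_m |x_im - x_jm| / 2 (1 minus the
    average identity-by-state of two diploid calls).
    ``jaccard``: dosages binarized to alt-allele presence (x > 0);
    d = 1 - |A and B| / |A or B| over markers where at least one of the
    pair carries the alternate allele.
    """
    x = geno.dosage.astype(float)
    if np.any(x < 0):
        raise ValueError("distance_matrix requires an imputed matrix")
    n, m = x.shape
    if method == "one_minus_ibs":
        d = np.abs(x[:, None, :] - x[None, :, :]).mean(axis=2) / 2.0 if n <= 400 else None
        if d is None:  # memory-lean path
            d = np.zeros((n, n))
            for i in range(n):
                d[i] = np.abs(x - x[i]).mean(axis=1) / 2.0
    elif method == "jaccard":
        b = (x > 0).astype(float)
        inter = b @ b.T
        row = b.sum(axis=1)
        union = row[:, None] + row[None, :] - inter
        empty = union == 0
        if empty.any():
            log.warning("jaccard: %d pairs share no alt allele; distance set to 0", int(empty.sum() - n))
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - np.where(union > 0, inter / np.where(union == 0, 1, union), 1.0)
    else:
        raise ValueError(f"unknown distance method {method!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(sample_ids=np.asarray(geno.sample_ids), values=d, method=method)


@dataclass
class ClusterTree:
    """Ward linkage over a distance matrix with Newick export."""

    sample_ids: np.ndarray
    linkage_matrix: np.ndarray

    def cut_at(self, k: int) -> np.ndarray:
        """1-based cluster labels at k clusters."""
        return cut_tree(self.linkage_matrix, n_clusters=k).ravel() + 1

    def to_newick(self) -> str:
        n = len(self.sample_ids)
        Z = self.linkage_matrix

        def node(i: int, parent_height: float) -> str:
            if i < n:
                return f"{self.sample_ids[i]}:{parent_height:.6g}"
            row = Z[i - n]
            h = row[2]
            left = node(int(row[0]), h)
            right = node(int(row[1]), h)
            return f"({left},{right}):{max(parent_height - h, 0.0):.6g}"

        root = 2 * n - 2
        h_root = Z[-1, 2]
        row = Z[-1]
        left = node(int(row[0]), h_root)
        right = node(int(row[1]), h_root)
        return f"({left},{right});"


def ward_tree(dist: DistanceMatrix) -> ClusterTree:
    """Ward minimum-variance hierarchical clustering of a dissimilarity matrix."""
    if len(dist.sample_ids) < 2:
        raise ValueError("need at least 2 samples to cluster")
    order = np.argsort(dist.sample_ids)  # deterministic tie-break by id
    values = dist.values[np.ix_(order, order)]
    Z = linkage(squareform(values, checks=False), method="ward")
    return ClusterTree(sample_ids=dist.sample_ids[order], linkage_matrix=Z)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def amova(dist: DistanceMatrix, groups: np.ndarray) -> pd.DataFrame:
    """Partition molecular variance among vs within groups.

    Excoffier-style sums of squares from squared pairwise distances:
    SS_total = (1/N) sum_{i<j} d^2; SS_within sums the analogous
    within-group terms; variance components from the mean squares with
    the unequal-size coefficient n_bar = (N - sum n_g^2 / N) / (G - 1).
    Negative components are truncated to zero for the percentage
    column only (raw values kept).
    """
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    G, N = len(labels), len(groups)
    if G < 2:
        raise ValueError("amova needs at least two groups")
    if np.all(counts < 2):
        raise ValueError("all groups are singletons")
    d2 = dist.values**2
    iu = np.triu_indices(N, k=1)
    ss_total = d2[iu].sum() / N
    ss_within = 0.0
    for g, n_g in zip(labels, counts):
        idx = np.where(groups == g)[0]
        if n_g < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(n_g, k=1)].sum() / n_g
    ss_among = ss_total - ss_within
    df_among, df_within = G - 1, N - G
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    n_bar = (N - (counts**2).sum() / N) / (G - 1)
    var_within = ms_within
    var_among = (ms_among - ms_within) / n_bar
    degenerate = ss_total < 1e-12
    raw = {"among": var_among, "within": var_within}
    clipped = {k: max(v, 0.0) for k, v in raw.items()}
    tot = clipped["among"] + clipped["within"]
    if degenerate or tot <= 0:
        pct = {"among": 0.0, "within": 0.0}
    else:
        pct = {k: 100.0 * v / tot for k, v in clipped.items()}
    table = pd.DataFrame(
        {
            "df": [df_among, df_within, df_among + df_within],
            "SS": [ss_among, ss_within, ss_total],
            "MS": [ms_among, ms_within, ms_among + ms_within],
            "est_var": [raw["among"], raw["within"], raw["among"] + raw["within"]],
            "pct_variation": [pct["among"], pct["within"], pct["among"] + pct["within"]],
        },
        index=["among", "within", "total"],
    )
    table.attrs["degenerate"] = bool(degenerate)
    table.attrs["negative_component"] = any(v < 0 for v in raw.values())
    return table


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

def _wc_components(x1: np.ndarray, x2: np.ndarray):
    """Per-locus Weir--Cockerham a, b, c variance components (2 populations).

    ``x1``, ``x2``: dosage matrices (missing as NaN allowed). Returns
    (a, b, c, valid) arrays over loci; ``valid`` is False where the
    locus is monomorphic across both groups or lacks calls.
    """
    r = 2.0

    def popstats(x):
        n = np.sum(~np.isnan(x), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p = np.nanmean(x, axis=0) / 2.0
            h = np.nanmean(x == 1, axis=0)
        return n, p, h

    n1, p1, h1 = popstats(x1)
    n2, p2, h2 = popstats(x2)
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    poly = (p_bar > 0) & (p_bar < 1)
    valid = poly & (n1 >= 2) & (n2 >= 2) & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, valid


def wc_fst(geno: GenotypeMatrix, mask1: np.ndarray, mask2: np.ndarray):
    """Weir--Cockerham theta between two sample sets.

    Returns ``(theta_multi, per_locus)`` where the multi-locus estimate
    is the ratio of sums sum(a) / sum(a+b+c); negative per-locus values
    are retained.
    """
    x = geno.dosage_float()
    a, b, c, valid = _wc_components(x[mask1], x[mask2])
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(valid & (denom != 0), a / denom, np.nan)
    if not valid.any():
        raise ValueError("no polymorphic locus with enough calls in both groups")
    theta = float(a[valid].sum() / denom[valid].sum())
    return theta, per_locus


def pairwise_fst(geno: GenotypeMatrix, groups: np.ndarray) -> pd.DataFrame:
    """Multi-locus Weir--Cockerham Fst for every pair of groups."""
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups) if (groups == g).sum() >= 2]
    if len(labels) < 2:
        raise ValueError("need at least two groups with >= 2 samples")
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            theta, _ = wc_fst(geno, groups == gi, groups == gj)
            out.loc[gi, gj] = out.loc[gj, gi] = theta
    return out
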