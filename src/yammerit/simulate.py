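"""Synthetic genotype/phenotype generator for a clonal yam breeding panel.

The generator emulates the statistical structure a landrace diversity
study assumes downstream: a panel of landraces plus elite checks drawn
from a small number of diverged ancestral clusters (Balding--Nichols
allele-frequency model, so the realized Weir--Cockerham Fst between pure
clusters is controlled by a single divergence parameter), dioecious sex
and flowering labels, and five correlated traits measured in a
replicated multi-season trial.

Phenotypes are generated on their natural scales (t/ha, AUDPC, scores,
percent) by affine transform of a latent genetic value built from a
sparse set of QTL with additive and heterozygote-dominance effects.
Trait correlation enters through a shared QTL pool. The trial layout is
a randomized complete block (season x replicate); residual variance is
set so the plot-level broad-sense heritability Vg/(Vg+Ve) matches the
per-trait target.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, MarkerPanel

TRAITS = ("yield", "ymv_audpc", "vigor", "oxidation", "dm")

#: Trait desirability used across the pipeline: +1 means larger is better.
DESIRABILITY = {"yield": 1, "ymv_audpc": -1, "vigor": 1, "oxidation": -1, "dm": 1}

_DEF_H2 = {"yield": 0.43, "ymv_audpc": 0.33, "vigor": 0.39, "oxidation": 0.44, "dm": 0.47}
_DEF_MEANS = {"yield": 10.54, "ymv_audpc": 333.5, "vigor": 2.79, "oxidation": 1.0, "dm": 30.3}
_DEF_SDS = {"yield": 7.15, "ymv_audpc": 60.57, "vigor": 0.46, "oxidation": 0.55, "dm": 3.10}

_NUCS = np.array(["A", "C", "G", "T"])


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic panel.

    Defaults emulate the reference design: 86 landraces + 16 elite
    clones, 4,432 SNPs on 20 chromosomes, K=3 ancestral clusters, two
    seasons x two replicates, five traits with broad-sense
    heritabilities between 0.33 and 0.47.
    """

    n_landraces: int = 86
    n_elite: int = 16
    n_markers: int = 4432
    n_chromosomes: int = 20
    K_true: int = 3
    fst_target: float = 0.15
    admix_fraction: float = 6 / 86
    female_fraction: float = 25 / 86
    nonflowering_fraction: float = 25 / 86
    n_seasons: int = 2
    n_reps: int = 2
    qtl_per_trait: int = 25
    qtl_overlap: float = 0.4
    dominance_ratio: float = 0.3
    h2_targets: dict = field(default_factory=lambda: dict(_DEF_H2))
    trait_means: dict = field(default_factory=lambda: dict(_DEF_MEANS))
    trait_sds: dict = field(default_factory=lambda: dict(_DEF_SDS))
    season_sd_frac: float = 0.25
    rep_sd_frac: float = 0.10
    missing_rate: float = 0.03
    depth_mean: float = 12.0
    simulate_depth: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("admix_fraction", "female_fraction", "nonflowering_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} must be in [0,1]")
        if self.female_fraction + self.nonflowering_fraction > 1.0 + 1e-12:
            raise InvalidConfigError("female + nonflowering fractions exceed 1")
        if self.K_true < 1:
            raise InvalidConfigError("K_true must be >= 1")
        if not 0.0 <= self.fst_target < 1.0:
            raise InvalidConfigError("fst_target must be in [0,1)")
        if self.n_markers < self.n_chromosomes:
            raise InvalidConfigError("n_markers must be >= n_chromosomes")
        for t, h2 in self.h2_targets.items():
            if not 0.0 < h2 <= 1.0:
                raise InvalidConfigError(f"h2_target for {t} must be in (0,1]")

    @property
    def n_samples(self) -> int:
        return self.n_landraces + self.n_elite

    @property
    def traits(self) -> tuple:
        return tuple(self.h2_targets)

    def rng(self, stage: str) -> np.random.Generator:
        """A generator deterministically derived from (seed, stage)."""
        tag = zlib.crc32(stage.encode("utf8"))
        ss = np.random.SeedSequence([self.seed, tag])
        return np.random.default_rng(ss)


@dataclass
class TrueModel:
    """Ground truth behind a simulated panel (for recovery experiments)."""

    ancestral_freqs: np.ndarray
    cluster_freqs: np.ndarray  # K x m
    Q_true: np.ndarray  # n x K ancestry proportions, rows sum to 1
    qtl_ids: dict = field(default_factory=dict)  # trait -> marker id array
    additive_effects: dict = field(default_factory=dict)  # trait -> a per QTL
    dominance_effects: dict = field(default_factory=dict)  # trait -> d per QTL
    sex: np.ndarray | None = None
    trait_genetic_values: pd.DataFrame | None = None


def generate_marker_panel(cfg: SimulationConfig, proportions: str = "dirichlet") -> MarkerPanel:
    """Lay markers on chromosomes with unequal (or forced-uniform) counts.

    Positions are strictly increasing within a chromosome; ids are
    ``chr{c}_{pos}`` and therefore unique.
    """
    rng = cfg.rng("panel")
    C, m = cfg.n_chromosomes, cfg.n_markers
    if proportions == "uniform":
        props = np.full(C, 1.0 / C)
    elif proportions == "dirichlet":
        props = rng.dirichlet(np.full(C, 4.0))
    else:
        raise ValueError(f"unknown proportions mode {proportions!r}")
    # one marker per chromosome guaranteed; remainder by largest share
    counts = np.maximum(1, np.floor(props * m).astype(int))
    while counts.sum() > m:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < m:
        deficit = props * m - counts
        counts[np.argmax(deficit)] += 1

    chrom, pos = [], []
    for c in range(1, C + 1):
        k = counts[c - 1]
        p = np.unique(rng.integers(1, 50_000_001, size=2 * k + 8))
        while len(p) < k:  # vanishingly rare at 5e7 positions
            p = np.unique(np.concatenate([p, rng.integers(1, 50_000_001, size=k)]))
        p = np.sort(rng.permutation(p)[:k])
        chrom.append(np.full(k, c))
        pos.append(p)
    chrom = np.concatenate(chrom)
    pos = np.concatenate(pos)
    ids = np.array([f"chr{c}_{p}" for c, p in zip(chrom, pos)])
    ref = rng.choice(_NUCS, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    nuc_idx = np.searchsorted(_NUCS, ref)
    alt = _NUCS[(nuc_idx + alt_shift) % 4]
    return MarkerPanel(marker_id=ids, chromosome=chrom, position=pos, ref_allele=ref, alt_allele=alt)


def generate_structured_genotypes(
    panel: MarkerPanel, cfg: SimulationConfig
) -> tuple[GenotypeMatrix, TrueModel]:
    """Draw dosages from a K-cluster Balding--Nichols admixture model.

    Ancestral frequencies come from a low-MAF-skewed Beta(1.4, 6)
    (clipped to [0.02, 0.98]); cluster frequencies from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F the divergence target, so that
    realized between-cluster Fst tracks ``fst_target``. Pure samples get
    one-hot ancestry rows, admixed samples Dirichlet rows. Each dosage
    is Binomial(2, sum_k Q_ik f_km); missingness is MCAR and depth is
    Poisson, both injected only so the QC filters have work to do.
    """
    if panel.n_markers == 0:
        raise ValueError("marker panel is empty")
    rng = cfg.rng("genotypes")
    n, m, K, F = cfg.n_samples, panel.n_markers, cfg.K_true, cfg.fst_target

    p_anc = np.clip(rng.beta(1.4, 6.0, size=m), 0.02, 0.98)
    if F > 0 and K > 1:
        shape1 = p_anc * (1 - F) / F
        shape2 = (1 - p_anc) * (1 - F) / F
        cluster_freqs = np.clip(rng.beta(shape1, shape2, size=(K, m)), 0.01, 0.99)
    else:
        cluster_freqs = np.clip(np.tile(p_anc, (K, 1)), 0.01, 0.99)

    Q = np.zeros((n, K))
    n_admix = int(round(cfg.admix_fraction * n))
    admixed = np.zeros(n, dtype=bool)
    if n_admix > 0:
        admixed[rng.choice(n, size=n_admix, replace=False)] = True
    labels = rng.integers(0, K, size=n)
    Q[np.arange(n), labels] = 1.0
    if n_admix > 0 and K > 1:
        Q[admixed] = rng.dirichlet(np.full(K, 1.5), size=n_admix)

    pi = Q @ cluster_freqs  # n x m expected allele frequency per sample
    dosage = rng.binomial(2, pi).astype(np.int8)

    depth = None
    if cfg.simulate_depth:
        depth = rng.poisson(cfg.depth_mean, size=(n, m))
    if cfg.missing_rate > 0:
        miss = rng.random((n, m)) < cfg.missing_rate
        dosage[miss] = MISSING

    ids = np.array(
        [f"LR{i + 1:03d}" for i in range(cfg.n_landraces)]
        + [f"EL{i + 1:02d}" for i in range(cfg.n_elite)]
    )
    geno = GenotypeMatrix(sample_ids=ids, panel=panel, dosage=dosage, depth=depth)
    model = TrueModel(ancestral_freqs=p_anc, cluster_freqs=cluster_freqs, Q_true=Q)
    return geno, model


def assign_sex_and_flowering(sample_ids: np.ndarray, cfg: SimulationConfig) -> pd.DataFrame:
    """Label each sample female / male / nonflowering, plus metadata.

    Counts are the largest-remainder rounding of the configured
    fractions, applied separately within the landrace and elite strata
    (so exact fractions give exact counts within each role), then
    shuffled under the seed. Samples beyond ``n_landraces`` are flagged
    as elite clones.
    """
    rng = cfg.rng("sex")
    n = len(sample_ids)
    fracs = np.array(
        [
            cfg.female_fraction,
            1.0 - cfg.female_fraction - cfg.nonflowering_fraction,
            cfg.nonflowering_fraction,
        ]
    )

    def allocate(size: int) -> np.ndarray:
        counts = np.floor(fracs * size).astype(int)
        rema = fracs * size - counts
        for _ in range(size - counts.sum()):
            i = int(np.argmax(rema))
            counts[i] += 1
            rema[i] = -1.0
        lab = np.repeat(np.array(["female", "male", "nonflowering"]), counts)
        return lab[rng.permutation(size)]

    n_land = min(cfg.n_landraces, n)
    labels = np.concatenate([allocate(n_land), allocate(n - n_land)])
    locations = rng.choice([f"region_{i:02d}" for i in range(1, 11)], size=n)
    role = np.array(
        ["landrace"] * cfg.n_landraces + ["elite"] * (n - cfg.n_landraces)
    )
    return pd.DataFrame(
        {
            "id": sample_ids,
            "location": locations,
            "sex": labels,
            "flowering": labels != "nonflowering",
            "role": role,
        }
    )


def _draw_qtl_effects(cfg: SimulationConfig, panel: MarkerPanel, rng: np.random.Generator):
    """Sample QTL positions and effects, with a shared pool across traits."""
    traits = cfg.traits
    q = min(cfg.qtl_per_trait, panel.n_markers)
    n_shared = int(round(cfg.qtl_overlap * q))
    shared_idx = rng.choice(panel.n_markers, size=n_shared, replace=False)
    shared_a = rng.normal(0.0, 1.0, size=n_shared)
    shared_d = rng.normal(0.0, cfg.dominance_ratio, size=n_shared)
    qtl_idx, add, dom = {}, {}, {}
    for t in traits:
        rest = np.setdiff1d(np.arange(panel.n_markers), shared_idx)
        own = rng.choice(rest, size=q - n_shared, replace=False)
        idx = np.concatenate([shared_idx, own]).astype(int)
        a = np.concatenate([shared_a, rng.normal(0.0, 1.0, size=q - n_shared)])
        d = np.concatenate([shared_d, rng.normal(0.0, cfg.dominance_ratio, size=q - n_shared)])
        qtl_idx[t], add[t], dom[t] = idx, a, d
    return qtl_idx, add, dom


def simulate_phenotypes(
    geno: GenotypeMatrix, model: TrueModel, cfg: SimulationConfig
) -> pd.DataFrame:
    """Generate plot-level phenotypes for genotype x season x rep.

    The latent genetic value of sample i for a trait is
    ``sum_q a_q (x_iq - 1) + d_q 1{x_iq = 1}`` over its QTL, rescaled so
    that on the trait's natural scale Vg = h2 * sd^2 and the plot
    residual variance is (1 - h2) * sd^2. Season and rep-within-season
    effects are additive blocks removed by the downstream trial model.

    Missing dosages at QTL are mode-imputed (with a warning) before the
    genetic value is formed. Side effect: fills the QTL fields and true
    genetic values of ``model``.
    """
    rng = cfg.rng("phenotypes")
    qtl_idx, add, dom = _draw_qtl_effects(cfg, geno.panel, rng)
    x = geno.dosage.astype(float)
    if (geno.dosage == MISSING).any():
        used = np.unique(np.concatenate(list(qtl_idx.values())))
        if (geno.dosage[:, used] == MISSING).any():
            warnings.warn("missing dosages at QTL markers; mode-imputing for the genetic value")
        for j in used:
            col = x[:, j]
            obs = col[col != MISSING]
            if obs.size == 0:
                col[:] = 0
                continue
            vals, cnt = np.unique(obs, return_counts=True)
            col[col == MISSING] = vals[np.argmax(cnt)]  # ties: smaller dosage (unique is sorted)
            x[:, j] = col

    n = geno.n_samples
    g_values = {}
    records = []
    genetic_table = {}
    for t in cfg.traits:
        idx = qtl_idx[t]
        a, d = add[t], dom[t]
        xq = x[:, idx]
        g = (xq - 1.0) @ a + (xq == 1.0) @ d
        sd_t = cfg.trait_sds[t]
        h2 = cfg.h2_targets[t]
        g_sd = g.std(ddof=1)
        if g_sd > 1e-12:
            g = (g - g.mean()) / g_sd * np.sqrt(h2) * sd_t
        else:
            g = np.zeros(n)
        g_values[t] = g
        genetic_table[t] = g
        model.qtl_ids[t] = np.asarray(geno.panel.marker_id)[idx]
        # effects on the trait's natural scale (post-standardization)
        scale = np.sqrt(h2) * sd_t / g_sd if g_sd > 1e-12 else 0.0
        model.additive_effects[t] = a * scale
        model.dominance_effects[t] = d * scale

    resid_sd = {t: np.sqrt(max(1.0 - cfg.h2_targets[t], 0.0)) * cfg.trait_sds[t] for t in cfg.traits}
    season_eff = {
        t: rng.normal(0.0, cfg.season_sd_frac * cfg.trait_sds[t], size=cfg.n_seasons)
        for t in cfg.traits
    }
    rep_eff = {
        t: rng.normal(0.0, cfg.rep_sd_frac * cfg.trait_sds[t], size=(cfg.n_seasons, cfg.n_reps))
        for t in cfg.traits
    }
    for s in range(cfg.n_seasons):
        for r in range(cfg.n_reps):
            row = {
                "genotype": geno.sample_ids,
                "season": np.full(n, s + 1),
                "rep": np.full(n, r + 1),
            }
            for t in cfg.traits:
                e = rng.normal(0.0, resid_sd[t], size=n)
                row[t] = cfg.trait_means[t] + g_values[t] + season_eff[t][s] + rep_eff[t][s, r] + e
            records.append(pd.DataFrame(row))
    plots = pd.concat(records, ignore_index=True)
    model.trait_genetic_values = pd.DataFrame(genetic_table, index=geno.sample_ids)
    return plots


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulated study produces."""

    config: SimulationConfig
    geno: GenotypeMatrix
    model: TrueModel
    metadata: pd.DataFrame
    plots: pd.DataFrame


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Run all four generator stages under one seed."""
    panel = generate_marker_panel(cfg)
    geno, model = generate_structured_genotypes(panel, cfg)
    metadata = assign_sex_and_flowering(geno.sample_ids, cfg)
    model.sex = metadata["sex"].to_numpy()
    plots = simulate_phenotypes(geno, model, cfg)
    return SimulatedDataset(config=cfg, geno=geno, model=model, metadata=metadata, plots=plots)


def write_phenotypes(plots: pd.DataFrame, path) -> None:
    plots.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path)
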