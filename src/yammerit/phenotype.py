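"""Trial analysis: genotype means, variance components, heritability.

Plot values follow a two-way model value = mu + genotype + env + error,
where env is the season-by-replicate block. BLUEs are least-squares
adjusted genotype means; BLUPs shrink them by the REML (or
expected-mean-squares) variance ratio. Broad-sense heritability is the
plot-basis H2 = Vg / (Vg + Ve); the narrow-sense estimate comes from a
genomic mixed model on the genotype means with a marker kinship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .mixed import fit_reml_kinship

log = logging.getLogger(__name__)


def _with_env(plots: pd.DataFrame) -> pd.DataFrame:
    df = plots.copy()
    df["env"] = df["season"].astype(str) + "_" + df["rep"].astype(str)
    return df


def _trait_columns(plots: pd.DataFrame, traits=None) -> list:
    if traits is not None:
        return list(traits)
    fixed = {"genotype", "season", "rep", "env"}
    return [c for c in plots.columns if c not in fixed]


def fit_genotype_means(plots: pd.DataFrame, mode: str = "blue", traits=None) -> pd.DataFrame:
    """One genotype-level value per trait: BLUEs or shrunken BLUPs.

    BLUE: least-squares adjusted means from value ~ genotype + env,
    i.e. model predictions for each genotype averaged over all env
    levels. BLUP: BLUE shrunk toward the grand mean by
    Vg / (Vg + Ve / r_g), with (Vg, Ve) from :func:`variance_components`
    and r_g the genotype's plot count.
    """
    if mode not in ("blue", "blup"):
        raise ValueError("mode must be 'blue' or 'blup'")
    df = _with_env(plots)
    traits = _trait_columns(df, traits)
    genos = pd.unique(df["genotype"])
    counts = df.groupby("genotype").size()
    single = counts[counts < 2]
    if len(single) > 0:
        log.warning("%d genotypes have a single plot (retained)", len(single))

    envs = pd.unique(df["env"])
    grid = pd.DataFrame(
        {"genotype": np.repeat(genos, len(envs)), "env": np.tile(envs, len(genos))}
    )
    out = pd.DataFrame(index=pd.Index(genos, name="genotype"))
    vc = variance_components(plots, traits=traits) if mode == "blup" else None
    for t in traits:
        sub = df.dropna(subset=[t])
        fit = smf.ols(f"Q('{t}') ~ C(genotype) + C(env)", data=sub).fit()
        pred = fit.predict(grid)
        blue = pred.groupby(grid["genotype"]).mean().reindex(genos)
        if mode == "blue":
            out[t] = blue
        else:
            vg, ve = vc.loc[t, "Vg"], vc.loc[t, "Ve"]
            r_g = counts.reindex(genos).astype(float)
            lam = vg / (vg + ve / r_g) if vg > 0 else 0.0
            mu = blue.mean()
            out[t] = mu + lam * (blue - mu)
    return out


def variance_components(plots: pd.DataFrame, traits=None, method: str = "auto") -> pd.DataFrame:
    """Genotypic and residual variance per trait.

    ``ems``: expected mean squares from the genotype/error ANOVA after
    removing env blocks — Vg = (MS_genotype - MS_error) / r with r the
    harmonic mean of plots per genotype, Ve = MS_error. ``reml``: REML
    via a random-genotype mixed model. ``auto`` uses EMS on (near-)
    balanced layouts and falls back to REML when plot counts vary by
    more than 10%.
    """
    df = _with_env(plots)
    traits = _trait_columns(df, traits)
    counts = df.groupby("genotype").size().astype(float)
    if counts.min() < 2:
        raise ValueError("variance_components needs >= 2 plots per genotype")
    r_h = len(counts) / (1.0 / counts).sum()
    unbalance = (counts.max() - counts.min()) / counts.mean()
    use = method
    if method == "auto":
        use = "ems" if unbalance <= 0.10 else "reml"

    rows = {}
    for t in traits:
        sub = df.dropna(subset=[t])
        if use == "ems":
            full = smf.ols(f"Q('{t}') ~ C(env) + C(genotype)", data=sub).fit()
            reduced = smf.ols(f"Q('{t}') ~ C(env)", data=sub).fit()
            ss_g = reduced.ssr - full.ssr
            df_g = sub["genotype"].nunique() - 1
            ms_g = ss_g / df_g
            ms_e = full.ssr / full.df_resid
            vg = (ms_g - ms_e) / r_h
            ve = ms_e
        else:
            md = smf.mixedlm(f"Q('{t}') ~ C(env)", data=sub, groups=sub["genotype"])
            fit = md.fit(reml=True, method="lbfgs")
            vg = float(fit.cov_re.iloc[0, 0])
            ve = float(fit.scale)
        truncated = vg < 0
        rows[t] = {"Vg": max(vg, 0.0), "Ve": ve, "r": r_h, "method": use,
                   "negative_vg_truncated": truncated}
        if truncated:
            log.warning("trait %s: negative Vg truncated to 0", t)
    return pd.DataFrame(rows).T.astype({"Vg": float, "Ve": float, "r": float})


@dataclass
class GeneticParameters:
    """Per-trait genetic parameter table (one row per trait)."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        header = "# H2 = Vg/(Vg+Ve); h2 genomic (kinship REML); CVg=100*sqrt(Vg)/mean\n"
        with open(path, "w") as fh:
            fh.write(header)
            self.table.to_csv(fh)


def genetic_parameters(
    vg: float, ve: float, mean: float, kinship: np.ndarray | None = None,
    blues: np.ndarray | None = None
) -> dict:
    """Derived parameters for one trait.

    Vp = Vg + Ve; H2 = Vg / Vp; CVg = 100 sqrt(Vg) / mean;
    CVp = 100 sqrt(Vp) / mean. When a kinship and genotype means are
    supplied, the narrow-sense h2 is the REML variance proportion of a
    genomic mixed model on the means.
    """
    if vg < 0 or ve < 0:
        raise ValueError("variance components must be nonnegative")
    vp = vg + ve
    out = {
        "Vg": vg,
        "Ve": ve,
        "Vp": vp,
        "H2": vg / vp if vp > 0 else np.nan,
        "mean": mean,
    }
    if mean > 0:
        out["CVg"] = 100.0 * np.sqrt(vg) / mean
        out["CVp"] = 100.0 * np.sqrt(vp) / mean
    else:
        log.warning("nonpositive mean: CVs undefined")
        out["CVg"] = np.nan
        out["CVp"] = np.nan
    if kinship is not None and blues is not None:
        y = np.asarray(blues, float)
        X = np.ones((len(y), 1))
        fit = fit_reml_kinship(y, X, kinship)
        out["h2"] = fit.h2
    else:
        out["h2"] = np.nan
    return out


def genetic_parameter_table(
    plots: pd.DataFrame, kinship: np.ndarray | None = None,
    blues: pd.DataFrame | None = None, traits=None
) -> GeneticParameters:
    """Assemble the full per-trait parameter table from plot data."""
    vc = variance_components(plots, traits=traits)
    traits = list(vc.index)
    rows = {}
    for t in traits:
        mean_t = float(plots[t].mean())
        b = blues[t].to_numpy() if blues is not None else None
        rows[t] = genetic_parameters(
            float(vc.loc[t, "Vg"]), float(vc.loc[t, "Ve"]), mean_t, kinship=kinship, blues=b
        )
    cols = ["H2", "h2", "Vg", "Ve", "Vp", "CVg", "CVp", "mean"]
    return GeneticParameters(table=pd.DataFrame(rows).T[cols])


def trait_correlations(blues: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations (and two-sided p-values) among genotype means.

    Missing values handled pairwise-complete; zero-variance traits give
    NaN entries.
    """
    from scipy import stats

    traits = list(blues.columns)
    if len(blues) < 3:
        raise ValueError("need >= 3 genotypes")
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            sub = blues[[a, b]].dropna()
            if len(sub) < 3 or sub[a].std() == 0 or sub[b].std() == 0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            rr, pp = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p
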