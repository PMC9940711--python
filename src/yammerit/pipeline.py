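"""End-to-end orchestration: qc -> diversity -> structure -> phenostats
-> gwas -> merit -> gpcp, driven by a YAML configuration.

Every numeric output file starts with a comment header recording the
stage, seed, and parameters, so a run can be audited from its artifacts
alone; a JSON manifest records versions, row counts, and the completed
stage list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, crosses, gwas, merit, phenotype, qc, simulate, structure

log = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "min_maf": 0.01,
    "max_missing": 0.10,
    "min_depth": 5,
    "k_min": 2,
    "k_max": 10,
    "membership_threshold": 0.70,
    "distance_method": "one_minus_ibs",
    "n_pcs": 3,
    "alpha": 0.05,
    "select_frac": 0.15,
    "desirability": dict(simulate.DESIRABILITY),
    "landraces_only_structure": True,
}

STAGES = ("qc", "diversity", "structure", "phenostats", "gwas", "merit", "gpcp")


@dataclass
class PipelineConfig:
    vcf: str
    phenotypes: str
    metadata: str
    out_dir: str
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged
        for s in STAGES:
            self.stages.setdefault(s, True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_inputs(self) -> None:
        needed = []
        if any(self.stages[s] for s in ("qc", "diversity", "structure", "gwas", "merit", "gpcp")):
            needed.append(self.vcf)
        if any(self.stages[s] for s in ("phenostats", "gwas", "merit", "gpcp")):
            needed.append(self.phenotypes)
        if self.stages["gpcp"] or self.params["landraces_only_structure"]:
            needed.append(self.metadata)
        for p in needed:
            if not Path(p).exists():
                raise FileNotFoundError(f"input required by an enabled stage missing: {p}")


def _write_csv(df: pd.DataFrame, path: Path, stage: str, seed: int, params: dict, index=True):
    with open(path, "w") as fh:
        fh.write(f"# yammerit v{__version__} stage={stage} seed={seed} params={json.dumps(params, sort_keys=True)}\n")
        df.to_csv(fh, index=index)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute enabled stages in order; return the run manifest."""
    cfg.validate_inputs()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed
    P = cfg.params
    manifest = {
        "version": __version__,
        "seed": seed,
        "params": P,
        "stages_completed": [],
        "row_counts": {},
    }

    def finish(stage):
        manifest["stages_completed"].append(stage)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        geno = qc.read_vcf(cfg.vcf)
        metadata = simulate.read_metadata(cfg.metadata) if Path(cfg.metadata).exists() else None

        if cfg.stages["qc"]:
            geno, report = qc.filter_markers(
                geno, min_maf=P["min_maf"], max_missing=P["max_missing"], min_depth=P["min_depth"]
            )
            _write_csv(report.to_frame(), out / "filter_report.csv", "qc", seed, report.params,
                       index=False)
            manifest["row_counts"]["markers_after_qc"] = geno.n_markers
            finish("qc")

        if cfg.stages["diversity"]:
            div = qc.diversity_by_chromosome(geno)
            _write_csv(div, out / "diversity.csv", "diversity", seed, {})
            manifest["row_counts"]["diversity_rows"] = len(div)
            finish("diversity")

        imputed = qc.impute_missing(geno, seed=seed)
        struct_geno = imputed
        if P["landraces_only_structure"] and metadata is not None:
            mask = np.isin(imputed.sample_ids,
                           metadata.loc[metadata["role"] == "landrace", "id"].to_numpy())
            if mask.sum() >= 10:
                struct_geno = imputed.subset_samples(mask)

        if cfg.stages["structure"]:
            n_pc = min(40, struct_geno.n_samples - 1, struct_geno.n_markers)
            scores, _, _ = structure.pca_genotypes(struct_geno, n_components=n_pc)
            bic, k_opt = structure.select_k_bic(
                scores, k_range=range(P["k_min"], P["k_max"] + 1), seed=seed
            )
            res = structure.admixture_em(struct_geno, K=k_opt, seed=seed)
            assign = structure.assign_membership(res.Q, threshold=P["membership_threshold"])
            dist = structure.distance_matrix(struct_geno, method=P["distance_method"])
            tree = structure.ward_tree(dist)
            labels = tree.cut_at(k_opt)
            label_map = dict(zip(tree.sample_ids, labels))
            hc_groups = np.array([label_map[s] for s in dist.sample_ids])
            am = structure.amova(dist, hc_groups)
            fst = structure.pairwise_fst(struct_geno, hc_groups)

            sp = {"k_opt": int(k_opt), "threshold": P["membership_threshold"],
                  "distance": P["distance_method"]}
            _write_csv(pd.DataFrame(res.Q, index=struct_geno.sample_ids,
                                    columns=[f"Q{k + 1}" for k in range(k_opt)]),
                       out / "q_matrix.csv", "structure", seed, sp)
            _write_csv(pd.DataFrame({"id": struct_geno.sample_ids, "assignment": assign}),
                       out / "assignment.csv", "structure", seed, sp, index=False)
            _write_csv(pd.DataFrame({"k": list(bic), "bic": list(bic.values())}),
                       out / "bic_curve.csv", "structure", seed, sp, index=False)
            (out / "tree.nwk").write_text(tree.to_newick() + "\n")
            _write_csv(am, out / "amova.csv", "structure", seed, sp)
            _write_csv(fst, out / "fst.csv", "structure", seed, sp)
            manifest["row_counts"]["k_opt"] = int(k_opt)
            finish("structure")

        blues = None
        if cfg.stages["phenostats"] or cfg.stages["gwas"] or cfg.stages["merit"] or cfg.stages["gpcp"]:
            plots = simulate.read_phenotypes(cfg.phenotypes)
            blues = phenotype.fit_genotype_means(plots, mode="blue")
            blues = blues.reindex(imputed.sample_ids).dropna(how="all")

        if cfg.stages["phenostats"]:
            K_all = gwas.vanraden_kinship(imputed.subset_samples(
                np.isin(imputed.sample_ids, blues.index.to_numpy())))
            gp = phenotype.genetic_parameter_table(plots, kinship=K_all, blues=blues)
            corr, pvals = phenotype.trait_correlations(blues)
            _write_csv(blues, out / "blues.csv", "phenostats", seed, {})
            _write_csv(gp.table, out / "genetic_parameters.csv", "phenostats", seed, {})
            _write_csv(corr, out / "trait_correlations.csv", "phenostats", seed, {})
            manifest["row_counts"]["genotype_means"] = len(blues)
            finish("phenostats")

        aligned = imputed.subset_samples(np.isin(imputed.sample_ids, blues.index.to_numpy())) \
            if blues is not None else None
        K = gwas.vanraden_kinship(aligned) if aligned is not None else None

        if cfg.stages["gwas"]:
            thr = gwas.significance_threshold(aligned.n_markers, alpha=P["alpha"])
            for t in blues.columns:
                y = blues.loc[list(aligned.sample_ids), t]
                rec = gwas.mlm_scan(y, aligned, K=K, n_pcs=P["n_pcs"])
                rec_naive = gwas.naive_scan(y, aligned)
                gp_par = {"trait": t, "threshold_lod": thr, "n_pcs": P["n_pcs"]}
                _write_csv(rec, out / f"gwas_mlm_{t}.csv", "gwas", seed, gp_par, index=False)
                _write_csv(rec_naive, out / f"gwas_naive_{t}.csv", "gwas", seed, gp_par,
                           index=False)
                sig = rec.loc[rec["LOD"] >= thr, "marker_id"]
                if len(sig) > 0:
                    eff = gwas.significant_snp_effects(y, aligned, sig)
                    _write_csv(eff, out / f"gwas_effects_{t}.csv", "gwas", seed, gp_par,
                               index=False)
            manifest["row_counts"]["gwas_markers"] = aligned.n_markers
            finish("gwas")

        if cfg.stages["merit"]:
            gvals = merit.genomic_genetic_values(blues.loc[list(aligned.sample_ids)], K)
            fm = merit.factor_analysis(gvals)
            n_sel = max(1, int(round(P["select_frac"] * len(gvals))))
            idx = merit.fai_blup(fm, P["desirability"], select_n=n_sel)
            gains = merit.selection_gain(gvals, idx.index[idx["selected"]], P["desirability"])
            mp = {"select_frac": P["select_frac"], "n_retained": fm.n_retained}
            _write_csv(idx, out / "merit_index.csv", "merit", seed, mp)
            _write_csv(fm.loadings, out / "factor_loadings.csv", "merit", seed, mp)
            _write_csv(
                pd.DataFrame({"eigenvalue": fm.eigenvalues},
                             index=[f"comp{i + 1}" for i in range(len(fm.eigenvalues))]),
                out / "factor_eigenvalues.csv", "merit", seed, mp)
            _write_csv(gains, out / "selection_gains.csv", "merit", seed, mp)
            manifest["row_counts"]["n_selected"] = int(idx["selected"].sum())
            finish("merit")

        if cfg.stages["gpcp"]:
            effects = crosses.estimate_ad_effects(blues.loc[list(aligned.sample_ids)], aligned)
            meta_f = metadata[metadata["id"].isin(aligned.sample_ids)]
            if P.get("landraces_only_gpcp", True):
                meta_f = meta_f[meta_f["role"] == "landrace"]
            pairs = crosses.enumerate_crosses(meta_f)
            preds = crosses.predict_all_crosses(aligned, effects, pairs)
            merits, parents = crosses.crossing_merit_summary(preds, weights=None)
            gpp = {"n_crosses": len(pairs)}
            _write_csv(merits, out / "cross_predictions.csv", "gpcp", seed, gpp, index=False)
            _write_csv(parents, out / "parent_summary.csv", "gpcp", seed, gpp, index=False)
            manifest["row_counts"]["n_crosses"] = len(pairs)
            finish("gpcp")
    except Exception as exc:
        manifest["failed"] = repr(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    return manifest


def simulate_to_dir(cfg: simulate.SimulationConfig, out_dir) -> dict:
    """Generate a synthetic study and write its VCF / phenotype / metadata files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate.simulate_dataset(cfg)
    qc.write_vcf(ds.geno, out / "genotypes.vcf")
    simulate.write_phenotypes(ds.plots, out / "phenotypes.tsv")
    simulate.write_metadata(ds.metadata, out / "metadata.csv")
    paths = {
        "vcf": str(out / "genotypes.vcf"),
        "phenotypes": str(out / "phenotypes.tsv"),
        "metadata": str(out / "metadata.csv"),
    }
    return paths
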