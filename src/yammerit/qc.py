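"""Genotype I/O, marker filtering, imputation, and diversity statistics.

Filtering follows the standard pipeline for a DArTseq-derived SNP
matrix: low-depth calls are masked first, then markers failing the
missingness ceiling are dropped, then markers below the MAF floor
(computed on nonmissing calls only).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, GenotypeMatrix, MarkerPanel, allele_frequencies

log = logging.getLogger(__name__)


class EmptyResultError(RuntimeError):
    """All markers (or samples) were removed by a filtering step."""

    def __init__(self, msg: str, report: "FilterReport | None" = None):
        super().__init__(msg)
        self.report = report


@dataclass
class FilterReport:
    """Per-stage marker/cell counts from :func:`filter_markers`."""

    n_markers_in: int = 0
    n_cells_depth_masked: int = 0
    n_removed_missing: int = 0
    n_removed_maf: int = 0
    n_markers_out: int = 0
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "depth_masked_cells", "missingness", "maf", "output"],
                "count": [
                    self.n_markers_in,
                    self.n_cells_depth_masked,
                    self.n_removed_missing,
                    self.n_removed_maf,
                    self.n_markers_out,
                ],
            }
        )


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Non-biallelic or non-SNP records are skipped (count logged). GT is
    coded as the number of alternate alleles; ``./.`` becomes missing.
    Per-sample DP is captured when the FORMAT declares it.
    """
    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    if samples.size == 0:
        raise ValueError(f"no samples in VCF {path}")
    ids, chroms, poss, refs, alts = [], [], [], [], []
    dosage_rows, depth_rows = [], []
    has_depth = False
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        ids.append(rec.ID if rec.ID not in (None, ".") else f"chr{rec.CHROM}_{rec.POS}")
        chrom = re.sub(r"^chr", "", str(rec.CHROM), flags=re.IGNORECASE)
        chroms.append(int(chrom) if chrom.isdigit() else 0)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gt = rec.gt_types  # 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dosage_rows.append(dos.astype(np.int8))
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            has_depth = True
            depth_rows.append(np.where(dp[:, 0] < 0, 0, dp[:, 0]))
        else:
            depth_rows.append(np.zeros(len(samples), dtype=int))
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    panel = MarkerPanel(
        marker_id=np.array(ids),
        chromosome=np.array(chroms, dtype=int),
        position=np.array(poss, dtype=int),
        ref_allele=np.array(refs),
        alt_allele=np.array(alts),
    )
    dosage = np.array(dosage_rows, dtype=np.int8).T if ids else np.zeros((len(samples), 0), np.int8)
    depth = np.array(depth_rows, dtype=int).T if (ids and has_depth) else None
    geno = GenotypeMatrix(sample_ids=samples, panel=panel, dosage=dosage, depth=depth)
    geno.n_skipped_records = n_skipped
    return geno


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeMatrix, path) -> str:
    """Write the matrix as unphased VCF v4.2 (GT, plus DP when present)."""
    for sid in geno.sample_ids:
        if re.search(r"\s", str(sid)):
            raise ValueError(f"sample id {sid!r} contains whitespace")
    has_depth = geno.depth is not None
    fmt = "GT:DP" if has_depth else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        for c in np.unique(geno.panel.chromosome):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.sample_ids))
            + "\n"
        )
        p = geno.panel
        for j in range(p.n_markers):
            cells = []
            for i in range(geno.n_samples):
                gt = _GT_STR[int(geno.dosage[i, j])]
                cells.append(f"{gt}:{int(geno.depth[i, j])}" if has_depth else gt)
            fh.write(
                f"{p.chromosome[j]}\t{p.position[j]}\t{p.marker_id[j]}\t"
                f"{p.ref_allele[j]}\t{p.alt_allele[j]}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )
    return str(path)


def filter_markers(
    geno: GenotypeMatrix,
    min_maf: float = 0.01,
    max_missing: float = 0.10,
    min_depth: int = 5,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the depth -> missingness -> MAF marker filters, in that order.

    Cells with read depth below ``min_depth`` are set missing (when a
    depth matrix exists); markers whose missing fraction exceeds
    ``max_missing`` are dropped; markers with minor-allele frequency
    below ``min_maf`` (on nonmissing calls) are dropped.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    report = FilterReport(
        n_markers_in=geno.n_markers,
        params={"min_maf": min_maf, "max_missing": max_missing, "min_depth": min_depth},
    )
    work = geno.copy()
    if work.depth is not None and min_depth > 0:
        low = (work.depth < min_depth) & (work.dosage != MISSING)
        work.dosage[low] = MISSING
        report.n_cells_depth_masked = int(low.sum())

    miss_frac = (work.dosage == MISSING).mean(axis=0)
    keep_miss = miss_frac <= max_missing
    report.n_removed_missing = int((~keep_miss).sum())
    work = work.subset_markers(keep_miss)

    p = allele_frequencies(work)
    maf = np.fmin(p, 1 - p)
    keep_maf = np.nan_to_num(maf, nan=-1.0) >= min_maf
    report.n_removed_maf = int((~keep_maf).sum())
    work = work.subset_markers(keep_maf)

    report.n_markers_out = work.n_markers
    if work.n_markers == 0:
        raise EmptyResultError("all markers removed by filtering", report)
    return work, report


def impute_missing(geno: GenotypeMatrix, method: str = "mode", seed: int = 0) -> GenotypeMatrix:
    """Fill missing calls per marker.

    ``mode`` (default): modal dosage, ties broken toward the smaller
    dosage. ``bernoulli``: two seeded Bernoulli(p) allele draws from the
    marker's alternate-allele frequency, for sensitivity checks.
    """
    work = geno.copy()
    miss = work.dosage == MISSING
    if not miss.any():
        return work
    rng = np.random.default_rng(seed)
    for j in np.where(miss.any(axis=0))[0]:
        col = work.dosage[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            raise ValueError(f"marker {work.panel.marker_id[j]} has no nonmissing call")
        if method == "mode":
            vals, cnt = np.unique(obs, return_counts=True)
            fill = vals[np.argmax(cnt)]  # np.unique sorts, so ties pick the smaller dosage
            col[col == MISSING] = fill
        elif method == "bernoulli":
            p = obs.mean() / 2.0
            k = int((col == MISSING).sum())
            col[col == MISSING] = rng.binomial(2, p, size=k).astype(np.int8)
        else:
            raise ValueError(f"unknown imputation method {method!r}")
    return work


def _site_stats(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-site p, Ho, He, MAF, PIC, and Nei gene diversity."""
    x = geno.dosage_float()
    n_obs = np.sum(~np.isnan(x), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(x, axis=0) / 2.0
        ho = np.nanmean(x == 1, axis=0)
    q = 1.0 - p
    he = 2.0 * p * q
    maf = np.fmin(p, q)
    pic = 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2
    with np.errstate(divide="ignore", invalid="ignore"):
        nei = np.where(n_obs > 1, n_obs / (n_obs - 1.0) * (1.0 - p**2 - q**2), np.nan)
    return pd.DataFrame(
        {
            "chromosome": geno.panel.chromosome,
            "p_alt": p,
            "Ho": ho,
            "He": he,
            "MAF": maf,
            "PIC": pic,
            "gene_diversity": nei,
        },
        index=geno.panel.marker_id,
    )


DIVERSITY_COLUMNS = ["n_snps", "Ho", "He", "MAF", "PIC", "gene_diversity"]


def diversity_by_chromosome(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-chromosome diversity summary with Total and Average rows.

    Per site: p is the alternate-allele frequency over nonmissing
    calls; Ho the heterozygote fraction; He = 2p(1-p); MAF = min(p,1-p);
    PIC = 1 - p^2 - q^2 - 2 p^2 q^2 (Botstein); gene diversity is the
    sample-size-corrected Nei estimator n/(n-1) * (1 - p^2 - q^2).
    Chromosome values are unweighted means over sites; the Average row
    is the unweighted mean of the chromosome rows; Total sums n_snps.
    """
    if geno.n_markers == 0:
        raise ValueError("no markers")
    sites = _site_stats(geno)
    groups = sites.groupby("chromosome")
    table = groups[["Ho", "He", "MAF", "PIC", "gene_diversity"]].mean()
    table.insert(0, "n_snps", groups.size())
    empty = set(np.unique(geno.panel.chromosome)) - set(table.index)
    if empty:
        log.warning("chromosomes with zero markers omitted: %s", sorted(empty))
    table.index = [f"Chr{c}" for c in table.index]
    total = pd.Series({"n_snps": table["n_snps"].sum()}, name="Total")
    avg = table.mean(axis=0)
    avg.name = "Average"
    out = pd.concat([table, total.to_frame().T, avg.to_frame().T])
    return out[DIVERSITY_COLUMNS]


def snp_density_table(geno: GenotypeMatrix, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Marker counts per genomic window (underlying table of a density plot)."""
    p = geno.panel
    rows = []
    for c in np.unique(p.chromosome):
        pos = p.position[p.chromosome == c]
        edges = np.arange(0, pos.max() + window_bp, window_bp)
        counts, _ = np.histogram(pos, bins=edges if len(edges) > 1 else [0, window_bp])
        for w, k in enumerate(counts):
            rows.append(
                {
                    "chromosome": int(c),
                    "window_start": int(w * window_bp) + 1,
                    "window_end": int((w + 1) * window_bp),
                    "n_snps": int(k),
                }
            )
    return pd.DataFrame(rows)
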