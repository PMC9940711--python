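"""Core in-memory containers for marker panels and genotype matrices.

Genotypes are stored as alternate-allele dosage (0, 1, 2) for diploid
samples, with ``-1`` marking a missing call. An optional per-cell read
depth matrix supports depth-based filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1


@dataclass(frozen=True)
class MarkerPanel:
    """Biallelic SNP marker map.

    Attributes
    ----------
    marker_id : array of str
        Unique identifiers, conventionally ``chr{c}_{pos}``.
    chromosome : array of int
        1-based chromosome numbers.
    position : array of int
        1-based physical positions (bp), strictly positive and strictly
        increasing within each chromosome.
    ref_allele, alt_allele : arrays of str
        Nucleotide symbols.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.marker_id)
        if len(np.unique(ids)) != len(ids):
            raise ValueError("marker ids must be unique")
        if np.any(np.asarray(self.position) <= 0):
            raise ValueError("positions must be strictly positive")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position": self.position,
                "ref_allele": self.ref_allele,
                "alt_allele": self.alt_allele,
            }
        )

    def subset(self, keep: np.ndarray) -> "MarkerPanel":
        """Return the panel restricted to a boolean or index selection."""
        return MarkerPanel(
            marker_id=np.asarray(self.marker_id)[keep],
            chromosome=np.asarray(self.chromosome)[keep],
            position=np.asarray(self.position)[keep],
            ref_allele=np.asarray(self.ref_allele)[keep],
            alt_allele=np.asarray(self.alt_allele)[keep],
        )


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with optional read depth.

    ``dosage`` holds values in {0, 1, 2} with ``-1`` for missing;
    ``depth`` (if present) holds nonnegative integer read depths of the
    same shape.
    """

    sample_ids: np.ndarray
    panel: MarkerPanel
    dosage: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows must match sample_ids")
        if m != self.panel.n_markers:
            raise ValueError("dosage columns must match panel size")
        bad = ~np.isin(self.dosage, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2} or -1 (missing)")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.dosage.shape:
                raise ValueError("depth shape must match dosage")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.panel.n_markers

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def dosage_float(self) -> np.ndarray:
        """Dosage as float with NaN for missing calls."""
        x = self.dosage.astype(float)
        x[self.dosage == MISSING] = np.nan
        return x

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            panel=self.panel.subset(keep),
            dosage=self.dosage[:, keep],
            depth=None if self.depth is None else self.depth[:, keep],
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids[keep],
            panel=self.panel,
            dosage=self.dosage[keep, :],
            depth=None if self.depth is None else self.depth[keep, :],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids.copy(),
            panel=self.panel,
            dosage=self.dosage.copy(),
            depth=None if self.depth is None else self.depth.copy(),
        )


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Alternate-allele frequency per marker over nonmissing calls.

    Markers with no nonmissing call get NaN.
    """
    x = geno.dosage_float()
    with np.errstate(invalid="ignore"):
        return np.nanmean(x, axis=0) / 2.0
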