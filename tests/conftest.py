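import numpy as np
import pytest

from yammerit import qc, simulate


@pytest.fixture(scope="session")
def small_cfg():
    return simulate.SimulationConfig(n_landraces=40, n_elite=5, n_markers=800, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def imputed_small(small_dataset):
    filt, _ = qc.filter_markers(small_dataset.geno)
    return qc.impute_missing(filt)


@pytest.fixture()
def toy_geno():
    """5 samples x 6 markers crafted so exactly 2 markers survive filtering.

    With min_maf=0.2 and max_missing=0.2 (no depth):
      m0: dosages (0,0,0,0,0)      -> MAF 0   -> removed (maf)
      m1: (0,1,2,1,0)              -> p=0.4   -> kept
      m2: (0,-1,-1,0,0) 40% miss   -> removed (missingness)
      m3: (2,2,2,2,1)              -> p=0.9, MAF 0.1 -> removed (maf)
      m4: (1,1,0,2,0)              -> p=0.4   -> kept
      m5: (0,0,0,0,1)              -> MAF 0.1 -> removed (maf)
    """
    from yammerit.containers import GenotypeMatrix, MarkerPanel

    panel = MarkerPanel(
        marker_id=np.array([f"chr1_{i + 1}0" for i in range(6)]),
        chromosome=np.ones(6, dtype=int),
        position=np.arange(10, 70, 10),
        ref_allele=np.array(list("AAAAAA")),
        alt_allele=np.array(list("CCCCCC")),
    )
    dosage = np.array(
        [
            [0, 0, 0, 2, 1, 0],
            [0, 1, -1, 2, 1, 0],
            [0, 2, -1, 2, 0, 0],
            [0, 1, 0, 2, 2, 0],
            [0, 0, 0, 1, 0, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        sample_ids=np.array([f"S{i}" for i in range(5)]), panel=panel, dosage=dosage
    )
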