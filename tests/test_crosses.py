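"""Cross prediction: effect estimation, Falconer F1 means, enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from yammerit import crosses, phenotype, simulate
from yammerit.crosses import CrossEffects, falconer_cross_mean
from yammerit.simulate import SimulationConfig


def _one_marker_effects(a, d, mu=0.0):
    eff = CrossEffects(marker_id=np.array(["m"]))
    eff.intercept["t"] = mu
    eff.additive["t"] = np.array([a], float)
    eff.dominance["t"] = np.array([d], float)
    return eff


def _f1_oracle(dos1, dos2, a, d):
    """Genotype-frequency enumeration: M = a(pp' - qq') + d(pq' + p'q)."""
    p, pp = dos1 / 2.0, dos2 / 2.0
    q, qq = 1 - p, 1 - pp
    return a * (p * pp - q * qq) + d * (p * qq + pp * q)


class TestFalconerFormula:
    def test_fixed_homozygous_cross(self):
        # both parents 1/1: all offspring carry dosage 2 -> M = a
        eff = _one_marker_effects(a=1.0, d=0.5)
        out = crosses.predict_cross_mean(np.array([2]), np.array([2]), eff)
        assert out["t"] == pytest.approx(1.0)

    def test_aa_by_aa_gives_d(self):
        # AA x aa: every offspring heterozygous -> M = d
        eff = _one_marker_effects(a=0.0, d=1.0)
        out = crosses.predict_cross_mean(np.array([2]), np.array([0]), eff)
        assert out["t"] == pytest.approx(1.0)

    def test_het_by_het(self):
        # Aa x Aa with a=2, d=1 -> 2*(0.25-0.25) + 1*0.5 = 0.5
        eff = _one_marker_effects(a=2.0, d=1.0)
        out = crosses.predict_cross_mean(np.array([1]), np.array([1]), eff)
        assert out["t"] == pytest.approx(0.5)

    @pytest.mark.parametrize("d1", [0, 1, 2])
    @pytest.mark.parametrize("d2", [0, 1, 2])
    def test_all_nine_combinations_match_oracle(self, d1, d2):
        a, d = 1.3, -0.7
        got = falconer_cross_mean(np.array([d1], float), np.array([d2], float),
                                  np.array([a]), np.array([d]))
        assert got == pytest.approx(_f1_oracle(d1, d2, a, d), abs=1e-12)

    def test_symmetry_in_parents(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        d = rng.normal(size=30)
        g1 = rng.integers(0, 3, 30).astype(float)
        g2 = rng.integers(0, 3, 30).astype(float)
        assert falconer_cross_mean(g1, g2, a, d) == pytest.approx(
            falconer_cross_mean(g2, g1, a, d), abs=1e-10
        )

    def test_selfing_limit_is_population_mean(self):
        # p' = p reduces to a(p-q) + 2pq d per marker
        rng = np.random.default_rng(1)
        a = rng.normal(size=10)
        d = rng.normal(size=10)
        g = rng.integers(0, 3, 10).astype(float)
        p = g / 2.0
        q = 1 - p
        expect = float((a * (p - q) + 2 * p * q * d).sum())
        assert falconer_cross_mean(g, g, a, d) == pytest.approx(expect, abs=1e-12)

    def test_strict_compat_differs_when_parents_differ(self):
        a = np.array([0.0])
        d = np.array([1.0])
        strict = falconer_cross_mean(np.array([2.0]), np.array([0.0]), a, d, strict_compat=True)
        assert strict != pytest.approx(1.0)  # printed form fails the AA x aa identity

    def test_missing_parent_genotype_rejected(self):
        eff = _one_marker_effects(1.0, 0.0)
        with pytest.raises(ValueError, match="missing"):
            crosses.predict_cross_mean(np.array([-1]), np.array([2]), eff)

    @settings(max_examples=50, derandomize=True)
    @given(
        dos=hnp.arrays(np.int8, (2, 8), elements=st.integers(0, 2)),
        eff=hnp.arrays(np.float64, (2, 8), elements=st.floats(-5, 5)),
    )
    def test_formula_equals_oracle_and_symmetry_property(self, dos, eff):
        """For any parent pair and effects, the Falconer form matches the
        genotype-frequency enumeration and is symmetric in the parents."""
        g1, g2 = dos[0].astype(float), dos[1].astype(float)
        a, d = eff[0], eff[1]
        got = falconer_cross_mean(g1, g2, a, d)
        oracle = float(_f1_oracle(g1, g2, a, d).sum())
        assert got == pytest.approx(oracle, abs=1e-9)
        assert got == pytest.approx(falconer_cross_mean(g2, g1, a, d), abs=1e-9)


class TestEffectEstimation:
    def _sim(self, seed, dominance_ratio=0.3, n=80, m=400):
        cfg = SimulationConfig(
            n_landraces=n, n_elite=0, n_markers=m, dominance_ratio=dominance_ratio,
            missing_rate=0.0, simulate_depth=False, seed=seed,
        )
        ds = simulate.simulate_dataset(cfg)
        blues = phenotype.fit_genotype_means(ds.plots)
        return ds, blues.loc[list(ds.geno.sample_ids)]

    def test_purely_additive_truth_keeps_dominance_small(self):
        ratios = []
        for seed in range(5):
            ds, blues = self._sim(seed, dominance_ratio=0.0)
            eff = crosses.estimate_ad_effects(blues[["dm"]], ds.geno)
            a = eff.additive["dm"]
            d = eff.dominance["dm"]
            ratios.append(np.linalg.norm(d) / max(np.linalg.norm(a), 1e-12))
        assert np.mean(ratios) < 0.3

    def test_causal_marker_sign_recovered(self):
        correct = 0
        trials = 0
        for seed in range(10):
            ds, blues = self._sim(100 + seed)
            eff = crosses.estimate_ad_effects(blues[["dm"]], ds.geno)
            ids = list(ds.geno.panel.marker_id)
            true_a = ds.model.additive_effects["dm"]
            top = np.argmax(np.abs(true_a))
            j = ids.index(ds.model.qtl_ids["dm"][top])
            trials += 1
            correct += np.sign(eff.additive["dm"][j]) == np.sign(true_a[top])
        assert correct / trials >= 0.9

    def test_null_trait_effects_shrunk(self):
        ds, blues = self._sim(7)
        rng = np.random.default_rng(9)
        null = pd.DataFrame({"noise": rng.normal(0, 1.0, len(blues))}, index=blues.index)
        eff = crosses.estimate_ad_effects(null, ds.geno)
        assert np.abs(eff.additive["noise"]).max() < 0.1 * null["noise"].std()


class TestEnumeration:
    def _meta(self, females, males, nonflowering):
        ids = [f"f{i}" for i in range(females)] + [f"m{i}" for i in range(males)] + [
            f"n{i}" for i in range(nonflowering)
        ]
        sex = ["female"] * females + ["male"] * males + ["nonflowering"] * nonflowering
        return pd.DataFrame(
            {"id": ids, "sex": sex, "flowering": [s != "nonflowering" for s in sex],
             "role": "landrace", "location": "x"}
        )

    def test_reference_design_count(self):
        pairs = crosses.enumerate_crosses(self._meta(25, 36, 25))
        assert len(pairs) == 900
        assert pairs.duplicated().sum() == 0

    def test_single_pair(self):
        assert len(crosses.enumerate_crosses(self._meta(1, 1, 0))) == 1

    def test_all_nonflowering_empty(self):
        assert len(crosses.enumerate_crosses(self._meta(0, 0, 5))) == 0


class TestMeritSummary:
    def _preds(self):
        rng = np.random.default_rng(2)
        pairs = crosses.enumerate_crosses(
            pd.DataFrame(
                {"id": ["f1", "f2", "m1", "m2"], "sex": ["female", "female", "male", "male"],
                 "flowering": True, "role": "landrace"}
            )
        )
        pairs["yield"] = rng.normal(10, 2, len(pairs))
        return pairs

    def test_single_trait_ranking_matches_f1_mean(self):
        preds = self._preds()
        merits, _ = crosses.crossing_merit_summary(preds, weights={"yield": 1.0})
        assert (merits.sort_values("total_merit")["yield"].diff().dropna() >= 0).all()

    def test_weight_sign_flip(self):
        preds = self._preds()
        plus, _ = crosses.crossing_merit_summary(preds, weights={"yield": 1.0})
        minus, _ = crosses.crossing_merit_summary(preds, weights={"yield": -1.0})
        assert np.allclose(plus["total_merit"], -minus["total_merit"])

    def test_best_additive_parent_tops_summary(self):
        # additive-only truth: one parent strictly better on the desirable trait
        from yammerit.containers import GenotypeMatrix, MarkerPanel

        m = 30
        panel = MarkerPanel(
            marker_id=np.array([f"chr1_{j + 1}" for j in range(m)]),
            chromosome=np.ones(m, dtype=int), position=np.arange(1, m + 1),
            ref_allele=np.full(m, "A"), alt_allele=np.full(m, "C"),
        )
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, (6, m)).astype(np.int8)
        dosage[0] = 2  # best female: homozygous for every favorable allele
        geno = GenotypeMatrix(
            sample_ids=np.array(["f_best", "f2", "f3", "m1", "m2", "m3"]),
            panel=panel, dosage=dosage,
        )
        eff = CrossEffects(marker_id=panel.marker_id)
        eff.intercept["t"] = 0.0
        eff.additive["t"] = np.abs(rng.normal(1, 0.2, m))
        eff.dominance["t"] = np.zeros(m)
        meta = pd.DataFrame(
            {"id": geno.sample_ids, "sex": ["female"] * 3 + ["male"] * 3,
             "flowering": True, "role": "landrace"}
        )
        pairs = crosses.enumerate_crosses(meta)
        preds = crosses.predict_all_crosses(geno, eff, pairs)
        _, parents = crosses.crossing_merit_summary(preds, weights={"t": 1.0})
        females = parents[parents["role"] == "female"]
        assert females.iloc[0]["parent"] == "f_best"


class TestProgenyRecovery:
    def test_predicted_means_track_simulated_f1(self):
        """Predicted cross means correlate with realized F1 progeny means."""
        rng = np.random.default_rng(10)
        m = 300
        a = rng.normal(0, 1, m)
        d = rng.normal(0, 0.4, m)
        parents = rng.integers(0, 3, (12, m)).astype(float)
        eff = CrossEffects(marker_id=np.array([f"m{j}" for j in range(m)]))
        eff.intercept["t"] = 0.0
        eff.additive["t"] = a
        eff.dominance["t"] = d

        pred, real = [], []
        pairs = [(i, j) for i in range(6) for j in range(6, 12)][:20]
        for i, j in pairs:
            pred.append(falconer_cross_mean(parents[i], parents[j], a, d))
            # simulate 200 F1: one gamete per parent per marker
            g1 = rng.binomial(1, np.tile(parents[i] / 2.0, (200, 1)))
            g2 = rng.binomial(1, np.tile(parents[j] / 2.0, (200, 1)))
            dos = g1 + g2
            vals = (dos - 1.0) @ a + (dos == 1) @ d
            real.append(vals.mean())
        assert np.corrcoef(pred, real)[0, 1] > 0.6
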