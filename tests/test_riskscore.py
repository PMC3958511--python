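import math

import numpy as np
import pytest

from corisk.mcl import GeneModule
from corisk.riskscore import (classify_risk, m_risk, module_null_p,
                              normal_reference, roc, s_risk, sample_z,
                              score_modules, truncate4, SampleRisk)
from corisk.synthetic import PlantedModule, SimulationConfig, simulate

from _oracles import auc_by_pair_counting
from conftest import dataset_with_significant_tumor_count, make_dataset


class TestTruncation:
    @pytest.mark.parametrize("k, rendered", [
        (28, 1.0), (27, 0.9642), (26, 0.9285), (25, 0.8928), (0, 0.0)])
    def test_table_rendering_of_proportions(self, k, rendered):
        assert truncate4(k / 28) == rendered

    def test_truncates_not_rounds(self):
        assert truncate4(0.96428) == 0.9642
        assert truncate4(0.99999) == 0.9999


class TestNormalReference:
    def test_degenerate_when_normals_identical(self):
        values = np.ones((2, 5))
        ds = make_dataset(values, n_tumor=2, n_normal=3)
        ref = normal_reference(ds, ["G1", "G2"])
        assert ref.mean == 1.0 and ref.degenerate

    def test_population_sd(self):
        # normal module-means (0, 2): x_bar = 1, sigma = 1 (ddof=0)
        values = np.array([[5.0, 5.0, 0.0, 2.0]])
        ds = make_dataset(values, n_tumor=2, n_normal=2)
        ref = normal_reference(ds, ["G1"])
        assert ref.mean == 1.0 and ref.sd == 1.0

    def test_single_gene_module_reduces_to_gene_values(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((1, 8))
        ds = make_dataset(values, n_tumor=4, n_normal=4)
        ref = normal_reference(ds, ["G1"])
        assert ref.mean == pytest.approx(values[0, 4:].mean())
        assert ref.sd == pytest.approx(values[0, 4:].std(ddof=0))


class TestSampleZ:
    @pytest.fixture
    def unit_ref_dataset(self):
        # module mean per sample equals the single gene's value
        values = np.array([[3.0, 1.0, 0.0, 2.0]])
        ds = make_dataset(values, n_tumor=2, n_normal=2)
        ref = normal_reference(ds, ["G1"])  # mean 1, sd 1
        return ds, ref

    def test_sample_at_reference_mean(self, unit_ref_dataset):
        ds, ref = unit_ref_dataset
        z, p = sample_z(ds, ["G1"], ref, "S2")
        assert z == 0.0 and p == 1.0

    def test_two_sigma_sample(self, unit_ref_dataset):
        ds, ref = unit_ref_dataset
        z, p = sample_z(ds, ["G1"], ref, "S1")
        assert z == pytest.approx(2.0)
        assert p == pytest.approx(0.0455, abs=1e-4)

    def test_critical_value_identity(self):
        # p(|Z| = 1.959964) = 0.05 via the erf series
        from corisk.riskscore import _two_sided_p
        assert _two_sided_p(1.959964) == pytest.approx(0.05, abs=1e-6)


class TestMRisk:
    @pytest.mark.parametrize("n_sig, exact, rendered", [
        (28, 1.0, 1.0), (27, 27 / 28, 0.9642), (26, 26 / 28, 0.9285),
        (25, 25 / 28, 0.8928), (0, 0.0, 0.0)])
    def test_proportion_of_significant_tumor_samples(self, n_sig, exact,
                                                     rendered):
        ds = dataset_with_significant_tumor_count(n_sig)
        risk = m_risk(["G1", "G2", "G3"], ds)
        assert risk.n_significant == n_sig
        assert risk.m_risk == exact
        assert risk.m_risk_rendered == rendered

    def test_invariant_to_gene_and_sample_order(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((4, 12))
        ds = make_dataset(values, n_tumor=6, n_normal=6)
        base = m_risk(["G1", "G3", "G4"], ds).m_risk
        assert m_risk(["G4", "G1", "G3"], ds).m_risk == base
        perm = np.r_[rng.permutation(6), 6 + rng.permutation(6)]
        ds_perm = make_dataset(values[:, perm], n_tumor=6, n_normal=6)
        assert m_risk(["G1", "G3", "G4"], ds_perm).m_risk == base


class TestModuleNullP:
    @pytest.fixture
    def null_dataset(self):
        rng = np.random.default_rng(8)
        return make_dataset(rng.standard_normal((30, 20)), n_tumor=10,
                            n_normal=10)

    def test_zero_m_risk_gives_p_one(self):
        ds = dataset_with_significant_tumor_count(0, n_tumor=8, n_normal=8)
        # widen the background with inert genes
        rng = np.random.default_rng(4)
        extra = rng.standard_normal((20, 16))
        values = np.vstack([ds.values, extra])
        ds2 = make_dataset(values, n_tumor=8, n_normal=8)
        p = module_null_p(["G1", "G2", "G3"], ds2, ds2.genes, draws=200,
                          seed=0)
        assert p == 1.0

    def test_determinism(self, null_dataset):
        args = (["G1", "G2", "G3"], null_dataset, null_dataset.genes)
        assert (module_null_p(*args, draws=500, seed=13)
                == module_null_p(*args, draws=500, seed=13))

    def test_background_smaller_than_module_rejected(self, null_dataset):
        with pytest.raises(ValueError, match="background"):
            module_null_p(["G1", "G2"], null_dataset, ["G1"], draws=10,
                          seed=0)

    def test_planted_shifted_module_recovers(self):
        cfg = SimulationConfig(
            n_genes=80, n_tumor=20, n_normal=20,
            modules=[PlantedModule(5, 0.7, 3.0)], seed=5)
        study = simulate(cfg)
        planted = study.truth["modules"][0]["genes"]
        p = module_null_p(planted, study.dataset,
                          study.truth["background_genes"], draws=2000,
                          seed=1)
        assert p < 0.05


class TestClassifyRisk:
    def test_table_grouping(self):
        ds28 = dataset_with_significant_tumor_count
        risks = [m_risk(["G1", "G2", "G3"], ds28(k)) for k in (28, 27, 26)]
        # 26/28 = 0.9285... <= 0.93 -> low; 27/28 -> middle; 28/28 -> high
        classify_risk(risks)
        assert [r.risk_class for r in risks] == ["high", "middle", "low"]


class TestSRisk:
    @pytest.fixture
    def two_module_setup(self):
        """Modules 1+2 shifted in tumors, modules 3+4 inert."""
        rng = np.random.default_rng(21)
        values = rng.standard_normal((12, 20))
        values[:6, :10] += 6.0  # strong tumor shift for genes of mods 1-2
        ds = make_dataset(values, n_tumor=10, n_normal=10)
        mods = [GeneModule(id=f"M{k}",
                           genes=frozenset(ds.genes[3 * k:3 * k + 3]))
                for k in range(4)]
        return ds, mods

    def test_extreme_scores_and_calls(self, two_module_setup):
        ds, mods = two_module_setup
        report = s_risk(ds, mods[:2])  # both modules shifted
        tumor_rows = [r for r in report if r.label == "tumor"]
        assert all(r.s_risk == 1.0 and r.call == "disease"
                   for r in tumor_rows)
        normal_rows = [r for r in report if r.label == "normal"]
        assert np.mean([r.s_risk for r in normal_rows]) < 0.3

    def test_fraction_below_call_threshold_stays_normal(self):
        row = SampleRisk(sample="s", label="tumor",
                         indicators=np.array([1, 1, 1, 0.0]),
                         s_risk=0.75, call="normal")
        assert row.s_risk == 3 / 4  # 0.75 < 0.8: not called disease

    def test_call_threshold_boundary(self, two_module_setup):
        ds, mods = two_module_setup
        # 4 modules, 2 shifted: tumor S_risk ~0.5 -> no disease call at 0.8
        report = s_risk(ds, mods)
        for r in report:
            assert (r.call == "disease") == (r.s_risk > 0.8)

    def test_soft_scores_average_one_minus_p(self, two_module_setup):
        ds, mods = two_module_setup
        report = s_risk(ds, mods[:2], soft=True)
        hard = s_risk(ds, mods[:2])
        for r_soft, r_hard in zip(report, hard):
            assert 0.0 <= r_soft.s_risk <= 1.0
        # strongly shifted tumor samples approach 1 either way
        assert report[0].s_risk == pytest.approx(1.0, abs=1e-6)

    def test_no_modules_is_an_error(self, two_module_setup):
        ds, _ = two_module_setup
        with pytest.raises(ValueError):
            s_risk(ds, [])

    def test_normal_leave_one_out_uses_other_normals(self):
        # one aberrant normal sample should flag itself, since its own
        # value is excluded from its reference
        rng = np.random.default_rng(2)
        values = rng.standard_normal((3, 12)) * 0.1
        values[:, -1] += 50.0  # last normal sample wildly off
        ds = make_dataset(values, n_tumor=6, n_normal=6)
        report = s_risk(ds, [GeneModule(id="M1", genes=frozenset(ds.genes))])
        assert report[-1].s_risk == 1.0


class TestRoc:
    def _risks(self, scores, labels):
        return [SampleRisk(sample=f"s{i}", label=l,
                           indicators=np.empty(0), s_risk=s, call="normal")
                for i, (s, l) in enumerate(zip(scores, labels))]

    def test_perfect_separation(self):
        r = roc(self._risks([0.9, 0.8, 0.2, 0.1],
                            ["tumor", "tumor", "normal", "normal"]))
        assert r.auc == pytest.approx(1.0)

    def test_all_tied_scores(self):
        r = roc(self._risks([0.5] * 6, ["tumor"] * 3 + ["normal"] * 3))
        assert r.auc == pytest.approx(0.5)

    def test_hand_counted_example(self):
        r = roc(self._risks([0.9, 0.8, 0.4, 0.3],
                            ["tumor", "normal", "tumor", "normal"]))
        assert r.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc(self._risks([0.1, 0.2], ["tumor", "tumor"]))

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(0)
        r = roc(self._risks(rng.random(50),
                            ["tumor" if x else "normal"
                             for x in rng.integers(0, 2, 50)]))
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_matches_mann_whitney_pair_counting(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            n = int(rng.integers(4, 20))
            labels = np.zeros(n, dtype=bool)
            labels[:max(1, n // 3)] = True
            rng.shuffle(labels)
            scores = rng.integers(0, 6, n) / 5.0  # coarse grid forces ties
            risks = self._risks(scores, ["tumor" if l else "normal"
                                         for l in labels])
            assert roc(risks).auc == pytest.approx(
                auc_by_pair_counting(scores, labels), abs=1e-12)


def test_score_modules_attaches_null_p_and_class(small_study):
    ds = small_study.dataset
    mods = [GeneModule(id=m["name"], genes=frozenset(m["genes"]))
            for m in small_study.truth["modules"]]
    scored = score_modules(mods, ds, small_study.truth["background_genes"],
                           draws=500, seed=3)
    assert all(s.null_p is not None and s.risk_class in
               {"high", "middle", "low"} for s in scored)
    shifted = {m["name"] for m in small_study.truth["modules"]
               if m["shifted"]}
    for s in scored:
        if s.module.id in shifted:
            assert s.null_p < 0.05
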