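"""PRS model construction, union, pruning and scoresum scoring."""

import numpy as np
import pandas as pd
import pytest

from smrprs import (
    CohortData,
    GwasSummary,
    PrsModel,
    ReferencePanel,
    build_functional_model,
    combine_models,
    ld_prune,
    score_cohort,
)
from smrprs.evaluate import auc_ci


def model_from(snps, weights, label="m", effect="A", other="G"):
    return PrsModel(
        table=pd.DataFrame(
            {
                "snp": snps,
                "effect_allele": effect,
                "other_allele": other,
                "weight": weights,
            }
        ),
        label=label,
    )


def make_cohort_data(dosages, labels, snps, a1="A", a2="G"):
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, len(snps) + 1) * 100,
            "id": snps,
            "a1": a1,
            "a2": a2,
        }
    )
    return CohortData(
        dosages=np.asarray(dosages, dtype=float),
        labels=np.asarray(labels),
        variants=variants,
        design="case_control",
    )


class TestBuildFunctionalModel:
    def _gwas(self, snps, betas):
        return GwasSummary(
            table=pd.DataFrame(
                {
                    "snp": snps,
                    "a1": "A",
                    "a2": "G",
                    "freq": 0.3,
                    "b": betas,
                    "se": 0.02,
                    "p": 1e-10,
                    "n": 1000,
                }
            )
        )

    def test_passing_top_snps_weighted_by_gwas(self):
        scan = pd.DataFrame(
            {
                "probe": ["p1", "p2", "p3", "p4"],
                "top_snp": ["rs1", "rs2", "rs3", "rs4"],
                "passed": [True, True, True, False],
            }
        )
        gwas = self._gwas(["rs1", "rs2", "rs3", "rs4"], [0.1, -0.2, 0.3, 0.4])
        model = build_functional_model(scan, gwas)
        assert model.snps == ["rs1", "rs2", "rs3"]
        assert list(model.table["weight"]) == [0.1, -0.2, 0.3]

    def test_shared_top_snp_across_scans_appears_once(self):
        scan = pd.DataFrame(
            {
                "probe": ["eqtl_p", "mqtl_p"],
                "top_snp": ["rs1", "rs1"],
                "passed": [True, True],
            }
        )
        model = build_functional_model(scan, self._gwas(["rs1"], [0.1]))
        assert model.snps == ["rs1"]

    def test_nothing_passed_gives_empty_model(self):
        scan = pd.DataFrame({"probe": ["p1"], "top_snp": ["rs1"], "passed": [False]})
        model = build_functional_model(scan, self._gwas(["rs1"], [0.1]))
        assert len(model) == 0

    def test_missing_gwas_variant_raises_with_ids(self):
        scan = pd.DataFrame({"probe": ["p1"], "top_snp": ["rsX"], "passed": [True]})
        with pytest.raises(KeyError, match="rsX"):
            build_functional_model(scan, self._gwas(["rs1"], [0.1]))


class TestCombineModels:
    def test_union_count_matches_established_plus_functional(self):
        # 313-variant established score + 149-variant functional score with
        # 5 shared variants -> 457 unique variants
        a = model_from([f"a{i}" for i in range(308)] + [f"s{i}" for i in range(5)],
                       0.1, label="gwas")
        b = model_from([f"s{i}" for i in range(5)] + [f"b{i}" for i in range(144)],
                       0.1, label="functional")
        assert len(a) == 313 and len(b) == 149
        combined = combine_models(a, b)
        assert len(combined) == 457

    def test_idempotent(self):
        a = model_from(["rs1", "rs2"], [0.1, 0.2])
        assert combine_models(a, a).table.equals(a.table)

    def test_disjoint_additivity(self):
        a = model_from([f"a{i}" for i in range(10)], 0.1)
        b = model_from([f"b{i}" for i in range(7)], 0.2)
        assert len(combine_models(a, b)) == 17

    def test_conflicting_weights_raise(self):
        a = model_from(["rs1"], [0.1])
        b = model_from(["rs1"], [0.2])
        with pytest.raises(ValueError, match="conflicting"):
            combine_models(a, b)

    def test_opposite_orientation_same_weight_accepted(self):
        a = model_from(["rs1"], [0.1], effect="A", other="G")
        b = model_from(["rs1"], [-0.1], effect="G", other="A")
        assert len(combine_models(a, b)) == 1


class TestLdPrune:
    def _panel(self, cols):
        ids = list(cols)
        variants = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, len(ids) + 1) * 1000,
                "id": ids,
                "a1": "A",
                "a2": "G",
                "maf": 0.3,
                "block": 0,
                "latent_rho": 0.0,
            }
        )
        return ReferencePanel(
            variants=variants, dosages=np.column_stack([cols[i] for i in ids]), seed=0
        )

    def test_perfect_ld_pair_keeps_earlier(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 500).astype(float)
        panel = self._panel({"A": x, "B": x.copy()})
        pruned = ld_prune(model_from(["A", "B"], [0.1, 0.2]), panel, 0.9)
        assert pruned.snps == ["A"]

    def test_low_ld_model_unchanged(self):
        rng = np.random.default_rng(1)
        panel = self._panel(
            {n: rng.integers(0, 3, 500).astype(float) for n in ("A", "B", "C")}
        )
        model = model_from(["A", "B", "C"], [0.1, 0.2, 0.3])
        assert ld_prune(model, panel, 0.9).snps == ["A", "B", "C"]

    def test_chain_keeps_ends(self):
        # A-B r2=0.95ish, B-C r2=0.95ish, A-C r2 lower: greedy keeps {A, C}
        rng = np.random.default_rng(2)
        n = 4000
        a = rng.standard_normal(n)
        e1, e2 = rng.standard_normal((2, n))
        b = 0.96 * a + np.sqrt(1 - 0.96**2) * e1
        c = 0.96 * b + np.sqrt(1 - 0.96**2) * e2
        cols = {k: 1.0 + 0.3 * v for k, v in (("A", a), ("B", b), ("C", c))}
        panel = self._panel(cols)
        r2 = panel.ld_r(["A", "B", "C"]) ** 2
        assert r2[0, 1] > 0.9 and r2[1, 2] > 0.9 and r2[0, 2] < 0.9
        pruned = ld_prune(model_from(["A", "B", "C"], [0.1, 0.2, 0.3]), panel, 0.9)
        assert pruned.snps == ["A", "C"]

    def test_subset_and_idempotent(self, multi_block_panel):
        v = multi_block_panel.variants
        model = model_from(list(v["id"]), 0.1)
        model.table["effect_allele"] = v["a1"].to_numpy()
        model.table["other_allele"] = v["a2"].to_numpy()
        pruned = ld_prune(model, multi_block_panel, 0.5)
        assert set(pruned.snps) <= set(model.snps)
        again = ld_prune(pruned, multi_block_panel, 0.5)
        assert again.snps == pruned.snps

    def test_missing_variant_raises(self):
        rng = np.random.default_rng(3)
        panel = self._panel({"A": rng.integers(0, 3, 100).astype(float)})
        with pytest.raises(KeyError, match="B"):
            ld_prune(model_from(["A", "B"], [0.1, 0.2]), panel, 0.9)


class TestScoreCohort:
    def test_hand_arithmetic(self):
        cohort = make_cohort_data([[2.0, 1.0], [0.0, 0.0]], [1, 0], ["rs1", "rs2"])
        model = model_from(["rs1", "rs2"], [0.5, -1.0])
        s = score_cohort(model, cohort)
        assert s.scores[0] == pytest.approx(0.5 * 2 - 1.0 * 1)
        assert s.scores[1] == 0.0

    def test_all_zero_dosages_score_zero(self):
        cohort = make_cohort_data(np.zeros((4, 3)), [1, 1, 0, 0], ["rs1", "rs2", "rs3"])
        s = score_cohort(model_from(["rs1", "rs2", "rs3"], [0.3, 0.2, -0.5]), cohort)
        assert np.all(s.scores == 0.0)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(11)
        dos = rng.integers(0, 3, (50, 4)).astype(float)
        cohort = make_cohort_data(dos, [1] * 25 + [0] * 25, ["a", "b", "c", "d"])
        w = [0.1, -0.3, 0.2, 0.05]
        s1 = score_cohort(model_from(["a", "b", "c", "d"], w), cohort)
        s2 = score_cohort(model_from(["a", "b", "c", "d"], [2 * x for x in w]), cohort)
        assert np.allclose(s2.scores, 2 * s1.scores)

    def test_allele_recode_leaves_auc_unchanged(self):
        rng = np.random.default_rng(12)
        dos = rng.integers(0, 3, (200, 3)).astype(float)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        cohort = make_cohort_data(dos, labels, ["a", "b", "c"])
        w = [0.4, -0.2, 0.1]
        s1 = score_cohort(model_from(["a", "b", "c"], w), cohort)
        recoded = PrsModel(
            table=pd.DataFrame(
                {
                    "snp": ["a", "b", "c"],
                    "effect_allele": "G",
                    "other_allele": "A",
                    "weight": [-x for x in w],
                }
            ),
            label="recoded",
        )
        s2 = score_cohort(recoded, cohort)
        # scores shift by a constant (sum 2*beta) so ranks and AUC match
        assert np.allclose(np.diff(np.sort(s1.scores)), np.diff(np.sort(s2.scores)))
        assert auc_ci(s1)[0] == pytest.approx(auc_ci(s2)[0], abs=1e-12)

    def test_exact_dot_product_oracle(self):
        rng = np.random.default_rng(13)
        dos = rng.integers(0, 3, (30, 5)).astype(float)
        snps = [f"rs{i}" for i in range(5)]
        cohort = make_cohort_data(dos, [1] * 15 + [0] * 15, snps)
        w = rng.normal(0, 0.2, 5)
        s = score_cohort(model_from(snps, w), cohort)
        expected = np.array(
            [sum(w[j] * dos[i, j] for j in range(5)) for i in range(30)]
        )
        assert np.allclose(s.scores, expected)

    def test_missing_dosage_imputed_at_twice_eaf(self):
        dos = np.array([[2.0], [1.0], [np.nan], [1.0]])
        cohort = make_cohort_data(dos, [1, 0, 1, 0], ["rs1"])
        s = score_cohort(model_from(["rs1"], [1.0]), cohort)
        observed_mean = (2.0 + 1.0 + 1.0) / 3  # = 2 * observed EAF
        assert s.scores[2] == pytest.approx(observed_mean)

    def test_absent_variants_skipped_with_count(self):
        cohort = make_cohort_data([[1.0], [2.0]], [1, 0], ["rs1"])
        s = score_cohort(model_from(["rs1", "rs_absent"], [0.5, 0.5]), cohort)
        assert s.n_variants_used == 1
        assert np.allclose(s.scores, [0.5, 1.0])

    def test_no_variants_present_raises(self):
        cohort = make_cohort_data([[1.0], [2.0]], [1, 0], ["rs1"])
        with pytest.raises(ValueError, match="no model variants"):
            score_cohort(model_from(["rsX"], [0.5]), cohort)
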